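"""Occurrence in space and time: the core-satellite bimodality.

Counts, for every species, the number of lakes (1-5) and hydrological
seasons (1-4) it was detected in, prints the joint distribution, and
deconstructs the count SAD by lake occupancy.
"""

from varzea import (
    abundance_vector,
    assign_seasons,
    deconstruct_sad,
    joint_occurrence_distribution,
    log10_class_histogram,
    occurrence_profiles,
    simulate_survey,
)

table, _ = simulate_survey(seed=1)
table = assign_seasons(table)
profiles = occurrence_profiles(table)
joint = joint_occurrence_distribution(profiles, n_lakes=5, n_seasons=4)
print("Species counts by (number of lakes, number of seasons) occupied:")
print(joint.matrix.to_string())
print(f"\nModal cells: {joint.modal_cells(2)}")
# one mode at (1,1) — transient species seen once in one lake and season —
# and one at (5,4) — persistent species present almost everywhere, always

hist = log10_class_histogram(abundance_vector(table, "individuals"))
tidy = deconstruct_sad(hist, profiles, group_by="lakes")
print("\nCount SAD split by lake occupancy (class, n_lakes, species):")
print(tidy.pivot(index="abundance_class", columns="group", values="n_species")
      .fillna(0).astype(int).to_string())
# occupancy rises along the abundance axis: the large classes are made of
# widespread species, the lowest class of single-lake transients
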