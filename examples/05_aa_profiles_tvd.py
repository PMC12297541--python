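"""Compare amino-acid distributions: TVD, goodness of fit, random-pairing null.

Simulates a repertoire where one (H, L) position pair carries a coupled
joint distribution, then (a) compares two study slices position-by-position
with Total Variation Distance and a binned chi-square goodness-of-fit test,
and (b) contrasts the coupled joint against the analytic random-pairing null.
"""

from pairedab import (
    PairedDataset,
    RepertoireConfig,
    joint_pair_distribution,
    pair_tvd,
    position_aa_distribution,
    position_gof_test,
    random_pairing_reference,
    simulate_paired_repertoire,
    total_variation_distance,
)

coupled_joint = {("A", "D"): 0.4, ("A", "E"): 0.1, ("V", "D"): 0.1, ("V", "E"): 0.4}
config = RepertoireConfig(
    n_cells=20_000, n_studies=2, seed=5,
    coupling=[("105", "105", coupled_joint)])
dataset = simulate_paired_repertoire(config)

# (a) dataset-vs-dataset comparison on one framework position
halves = [PairedDataset([r for r in dataset if r.study_id == s]) for s in ("study00", "study01")]
d1 = position_aa_distribution(halves[0], "H", "40")
d2 = position_aa_distribution(halves[1], "H", "40")
tvd_40 = total_variation_distance(d1, d2)
stat, df, p = position_gof_test(d1, d2)
print(f"H position 40, study00 vs study01 (same stated world):")
print(f"  TVD = {tvd_40:.4f} (0 = identical distributions)")
print(f"  goodness-of-fit chi-square = {stat:.2f} (df={df}, p={p:.3f}) -> no real difference")

# (b) coupled position pair vs the random-pairing null
obs = joint_pair_distribution(dataset, "105", "105")
ref = random_pairing_reference(dataset, "105", "105", mode="analytic")
print(f"\n(H 105, L 105) coupled pair, n={obs.n}:")
print(f"  observed joint: { {f'{h}{l}': round(v, 3) for (h, l), v in sorted(obs.joint.items())} }")
print(f"  TVD vs random pairing = {pair_tvd(obs, ref):.3f} "
      "(configured coupling implies 0.30; random pairing would give ~0)")
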