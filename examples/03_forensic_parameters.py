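"""Per-locus forensic parameters, combined powers and HWE testing."""

from strpopgen import (
    SimConfig,
    combined_powers,
    forensic_params,
    generate_dataset,
    hwe_test_table,
)

table, _ = generate_dataset(SimConfig(n_samples=300, n_males=250, seed=2))

df = forensic_params(table, level="length")
print(df[["marker", "h_obs", "h_exp", "pic", "pm", "pd", "pe", "tpi"]]
      .head(5).round(4).to_string(index=False))

cp = combined_powers(df)
print(f"\nacross {cp.n_loci} loci: CPE = {cp.cpe_repr}, CPD = {cp.cpd_repr}")
# The residuals (1 - CPE, 1 - CPD) are the chance a random person escapes
# exclusion / matches by chance across the whole panel.

hwe = hwe_test_table(table, "length", alpha=0.05, n_permutations=2000, seed=0)
print(f"\nHWE: {int(hwe['deviates'].sum())} of {len(hwe)} loci deviate "
      f"after Bonferroni (threshold {hwe['bonferroni_threshold'].iloc[0]:.6f})")
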