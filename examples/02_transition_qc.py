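"""QC-filter a constructed MRM transition report and quantify in fmol."""

from admarker.quant import (
    LinearitySeries,
    collision_energy,
    linearity_pass,
    quantify_report,
)
from admarker.synth import TransitionReportSpec, generate_transition_report

spec = TransitionReportSpec(n_clean=12, n_low_intensity=3, n_not_coeluted=2, n_asymmetric=1)
report, _ = generate_transition_report(spec, seed=0)

kept = quantify_report(report)
print(f"{len(report)} transitions -> kept {len(kept)}; "
      f"excluded per rule: {kept.attrs['qc_tally']}")
print("first quantified rows (endogenous fmol = PAR x SIS spiked):")
print(kept[["peptide_id", "par", "spike_fmol", "fmol"]].head(3).to_string(index=False))

# spike-level linearity: every PAR must sit strictly inside (0.1, 1)
good = LinearitySeries("PEP_OK", par_at_level=(0.15, 0.3, 0.6, 0.95))
bad = LinearitySeries("PEP_EDGE", par_at_level=(0.1, 0.2, 0.4, 0.8))
print(f"linearity pass {good.peptide_id}: {linearity_pass(good)}; "
      f"{bad.peptide_id}: {linearity_pass(bad)} (PAR 0.1 is outside the open window)")

print(f"collision energy at m/z 500, charge 2: {collision_energy(500, 2):.1f} V; "
      f"m/z 600, charge 3: {collision_energy(600, 3):.1f} V")
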