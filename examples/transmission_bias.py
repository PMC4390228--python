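"""Test CNV-haplotype transmission counts against 50:50 segregation.

Applies the continuity-corrected Pearson chi-square to two observed
count pairs of (CNV-haplotype, normal-haplotype) transmissions from
carrier parents, and shows a length-stratified transmission table built
from simulated phased families.
"""

from cnphase import SimulationParams, simulate_dataset, transmission_bias_test
from cnphase.pipeline import run_analysis, run_phasing
from cnphase.synthetic_families import write_dataset
import tempfile
from pathlib import Path

for n_cnv, n_normal in ((580, 671), (70, 98)):
    stat, p = transmission_bias_test(n_cnv, n_normal)
    rate = 100 * n_cnv / (n_cnv + n_normal)
    print(f"{n_cnv} CNV vs {n_normal} normal transmissions: "
          f"rate {rate:.1f}%, chi2 = {stat:.2f}, p = {p:.3f}")
print()

params = SimulationParams(seed=17, n_families=40, regions_per_family=4)
with tempfile.TemporaryDirectory() as tmp:
    paths = write_dataset(simulate_dataset(params), Path(tmp))
    outcomes, _ = run_phasing(
        paths["genotypes"], paths["calls_a"], paths["calls_b"], paths["pedigree"],
        keep_going=True,
    )
    table = run_analysis(outcomes)["transmissions"]

frame = table.to_frame()
cols = ["length_bin", "all_cnv", "all_total", "all_rate", "all_p", "all_p_adj"]
print(frame[cols].to_string(index=False))

# Both observed count pairs deviate significantly from 50:50 before
# correction for multiple testing (p = 0.011 and p = 0.037).  The
# simulated table sits near 50% in every length bin because the simulator
# transmits haplotypes without bias; the adjusted p-values are Bonferroni.
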