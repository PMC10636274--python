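"""Simulate a labeled-glutamine mzML run and quantify it end to end.

Writes a synthetic high-resolution run with a known 50/50 mixture of
unlabeled and U-13C5 glutamine plus mild noise, then runs the full
pipeline: EIC extraction, composite-peak location, shared-bounds
integration, MID calculation, natural-abundance correction and APE.
"""

import tempfile
from pathlib import Path

import numpy as np

from midquant import parse_formula
from midquant.method import Method, MzTolerance, TargetIon, TracerSpec
from midquant.pipeline import process_file
from midquant.synthetic import TruthSpec, write_synthetic_run

target = TargetIon(
    compound_name="glutamine",
    ion_name="Gln [M+H]+",
    formula=parse_formula("C5H11N2O3"),
    charge=1,
    base_mz=147.07642,
    tracers=(TracerSpec("C", 13, 5),),
    expected_rt=60.0,
    rt_window=20.0,
    is_characteristic=True,
    quantified_isotopologues=[0, 1, 2, 3, 4, 5],
)
method = Method(targets=[target], mz_tolerance=MzTolerance(10, "ppm"),
                resolution_mode="high_res")

truth = TruthSpec(
    target_name="Gln [M+H]+",
    label_distribution=np.array([0.5, 0, 0, 0, 0, 0.5]),
    apex_rt=60.0, sigma=4.0, apex_intensity=1e6,
    sigma_mult=0.02, sigma_add=5e3,
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "gln_50pct_U13C.mzML"
    write_synthetic_run([truth], method, path, seed=42)
    record = process_file(path, method)[0]

print("flags:         ", record.flags)
print("areas:         ", np.round(record.areas, 0))
print("raw MID:       ", np.round(record.raw_mid, 4))
print("corrected MID: ", np.round(record.corrected_mid, 4))
print("APE (13C):     ", f"{record.ape_percent[0]:.2f} %")
print()
print("The corrected MID returns the simulated 50/50 label mixture and the")
print("average percent enrichment is ~50%: half of all carbon positions")
print("carry 13C label.")
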