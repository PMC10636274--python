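"""Process a small batch with metadata: group statistics and comparisons.

Simulates two experimental groups of three replicates each (20% vs 40%
U-13C5 glutamine labeling plus an unlabeled control), runs the batch
driver, and prints the per-group MID summaries, the Welch t-test between
groups, and the unlabeled-control QC.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from midquant import parse_formula
from midquant.method import Method, MzTolerance, TargetIon, TracerSpec, save_method
from midquant.pipeline import BatchConfig, run_batch
from midquant.synthetic import TruthSpec, write_synthetic_run

target = TargetIon(
    compound_name="glutamine", ion_name="Gln [M+H]+",
    formula=parse_formula("C5H11N2O3"), charge=1, base_mz=147.07642,
    tracers=(TracerSpec("C", 13, 5),), expected_rt=60.0, rt_window=20.0,
    is_characteristic=True, quantified_isotopologues=[0, 1, 2, 3, 4, 5])
method = Method(targets=[target], mz_tolerance=MzTolerance(10, "ppm"),
                resolution_mode="high_res")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    save_method(method, tmp / "method.json")
    meta_rows = ["sample_id,file,group,time_point,is_unlabeled_control"]
    samples = {"ctl": (0.0, "control", True)}
    for i in range(3):
        samples[f"low{i}"] = (0.2, "low", False)
        samples[f"high{i}"] = (0.4, "high", False)
    for i, (name, (label, group, is_ctl)) in enumerate(samples.items()):
        x = np.array([1 - label, 0, 0, 0, 0, label])
        write_synthetic_run(
            [TruthSpec("Gln [M+H]+", x, apex_rt=60.0, sigma=4.0,
                       apex_intensity=1e6, sigma_mult=0.01)],
            method, tmp / f"{name}.mzML", seed=100 + i)
        meta_rows.append(f"{name},{name}.mzML,{group},0,{is_ctl}")
    (tmp / "meta.csv").write_text("\n".join(meta_rows) + "\n")

    run_batch(BatchConfig(
        method_path=str(tmp / "method.json"),
        data_paths=[str(tmp / "*.mzML")],
        output_dir=str(tmp / "out"),
        meta_path=str(tmp / "meta.csv"),
        comparisons=[("low", "high")],
    ))

    stats = pd.read_csv(tmp / "out" / "results_csv" / "GroupStats.csv")
    comps = pd.read_csv(tmp / "out" / "results_csv" / "Comparisons.csv")
    qc = pd.read_csv(tmp / "out" / "results_csv" / "QC.csv")

print("per-group mean corrected MID (channel 5 = U-13C5):")
print(stats[stats.channel == 5][["group", "mean_mid", "sd_mid", "n"]]
      .to_string(index=False))
print()
print("Welch t-test low vs high, M+5 channel:")
print(comps[comps.channel == "M+5"][["channel", "t", "p", "p_adj"]]
      .to_string(index=False))
print()
print("unlabeled-control QC (RMSE of raw MID vs natural background):")
print(qc.to_string(index=False))
print()
print("The M+5 means sit at the simulated 0.2 and 0.4 label fractions, the")
print("t-test flags the difference, and the control's RMSE near zero shows")
print("the instrument model and integration are unbiased.")
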