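"""The file-based pipeline end to end, in a temporary directory.

Writes four serial phantom exams as NIfTI + JSON sidecars, runs the
extraction stage (maps -> FTV/SPH/BPE per exam), and prints the
resulting longitudinal feature table — the same flow the
``dce-response extract`` command runs on real exam directories.
"""

import tempfile
from pathlib import Path

from dce_response import PhantomSpec, generate_longitudinal_exams, write_exam
from dce_response.pipeline import PipelineConfig, run_extract

with tempfile.TemporaryDirectory() as tmp:
    series_dir = Path(tmp) / "series"
    spec = PhantomSpec(noise_sd=15.0, seed=3)
    for series, truth in generate_longitudinal_exams(spec, patient_id="PH000"):
        write_exam(series, truth, series_dir)

    cfg = PipelineConfig(series_dir=str(series_dir), out_dir=str(Path(tmp) / "out"))
    features = run_extract(cfg)

print(features.drop(columns="qc_flags").round(3).to_string(index=False))
print(
    "\nOne row per (patient, timepoint).  FTV and LD shrink over treatment\n"
    "(the phantom tumor responds); SPH drifts up as the residual mask gets\n"
    "blockier; BPE stays near the generative 30% parenchymal enhancement."
)
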