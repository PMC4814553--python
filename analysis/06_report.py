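"""Aggregate every stage's outputs into summary.json and report.md."""

import warnings
from pathlib import Path

from perceptdcm.config import load_config
from perceptdcm.pipeline import stage_report

HERE = Path(__file__).parent

if __name__ == "__main__":
    cfg = load_config(HERE / "config.yaml")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = stage_report(cfg)
    print(f"report written to {cfg.results_dir}/report.md "
          f"(config hash {summary['config_hash']})")
    ex = summary["bms"]["all"]["exceedance"]
    print("exceedance:", {k: round(v, 4) for k, v in ex.items()})
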