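"""Generate the synthetic cohort: events, press streams, region BOLD.

Writes one directory per subject (events.tsv, bold_regions.tsv, truth.json)
plus a cohort manifest under data/.
"""

import warnings
from pathlib import Path

from perceptdcm.config import load_config
from perceptdcm.pipeline import stage_simulate

HERE = Path(__file__).parent

if __name__ == "__main__":
    cfg = load_config(HERE / "config.yaml")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = stage_simulate(cfg)
    counts = manifest["cohort"].value_counts().to_dict()
    print(f"simulated {len(manifest)} subjects "
          f"({counts.get('young', 0)} young, {counts.get('older', 0)} older) "
          f"into {cfg.data_dir}/")
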