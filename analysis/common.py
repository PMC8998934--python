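"""Shared helpers for the numbered analysis scripts."""

from pathlib import Path

import yaml

HERE = Path(__file__).resolve().parent
ROOT = HERE.parent


def load_config() -> dict:
    cfg = yaml.safe_load((HERE / "config.yaml").read_text())
    cfg["cohort_dir"] = ROOT / cfg["cohort_dir"]
    return cfg


def session_ids(cfg: dict):
    for a in range(cfg["n_animals"]):
        for week in cfg["weeks"]:
            yield f"a{a + 1:02d}", int(week)
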