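"""Shared plumbing for the numbered analysis drivers."""

import os

from meqtlmr.pipeline import load_config, run_pipeline

_CFG_PATH = os.path.join(os.path.dirname(__file__), "config.yaml")


def load_cfg():
    return load_config(_CFG_PATH)


def run_stages(stages):
    cfg = load_cfg()
    cfg["stages"] = stages
    out = run_pipeline(cfg, out_dir=cfg["out_dir"])
    return cfg, out
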