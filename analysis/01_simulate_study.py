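"""Generate the synthetic training study.

Simulates the full two-group design — concurrent vs post-trial visual
feedback, 10 and 11 participants, two sessions (simple 1:1 and
complicated 2:1 lifting/thrusting), each with a pre-test, eight training
trials and a post-test — and writes the trace CSV tree plus its manifest
under results/data/.
"""

from pathlib import Path

from ames import RunConfig, simulate_study, write_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"

if __name__ == "__main__":
    cfg = RunConfig(seed=1)
    dataset = simulate_study(cfg.design(), cfg.params_by_group(), seed=cfg.seed)
    manifest = write_dataset(dataset, OUT)
    cfg.to_yaml(OUT / "config_used.yaml")
    print(f"wrote {len(dataset)} traces ({len(dataset) // 20} participants x 20 phases)")
    print(f"manifest: {manifest}")
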