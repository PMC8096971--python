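"""Shared helpers for the numbered analysis drivers."""

from pathlib import Path

from fatebind.synth import GeneratorConfig, generate_workspace

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def get_workspace(perturbation="none"):
    """The study's default synthetic conditions (regenerated, deterministic)."""
    return generate_workspace(GeneratorConfig(seed=SEED, perturbation=perturbation))


def save(df, name, index=False):
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=index)
    print(f"  wrote {path}")
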