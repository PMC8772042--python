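"""Regenerate the packaged default probability model.

The packaged model is trained on synthetic order-0 Markov genomes from
the package's own community generator (a documented stand-in for a
reference-genome training corpus).  Run from the repository root:

    python scripts/train_default_model.py
"""

from pathlib import Path

from recurbin.prob_model import save_model, train_model
from recurbin.synthetic_data import SyntheticCommunitySpec, generate_genomes

TRAIN_SEED = 20260922
N_GENOMES = 12
GENOME_LENGTH = 150_000
DIVERGENCE = 0.9

OUT = Path(__file__).resolve().parent.parent / "src" / "recurbin" / "data" / "default_model.json"


def main() -> None:
    spec = SyntheticCommunitySpec(
        n_genomes=N_GENOMES,
        genome_length=GENOME_LENGTH,
        signature_divergence=DIVERGENCE,
        rng_seed=TRAIN_SEED,
    )
    genomes = generate_genomes(spec)
    model = train_model(
        genomes,
        rng_seed=TRAIN_SEED,
        training_meta={
            "source": "synthetic order-0 Markov genomes (packaged stand-in corpus)",
            "n_genomes": N_GENOMES,
            "genome_length": GENOME_LENGTH,
            "signature_divergence": DIVERGENCE,
        },
    )
    save_model(model, OUT)
    print(f"default model written to {OUT}")


if __name__ == "__main__":
    main()
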