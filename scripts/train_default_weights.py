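"""Reproduce the packaged SRCNN weight file.

Usage: python scripts/train_default_weights.py [--epochs N] [--seed S]
Writes src/ramanpc/data/default_weights.json (text container).
"""

import argparse
from pathlib import Path

from ramanpc.srcnn import make_patch_pairs, save_weights, train_srcnn
from ramanpc.srcnn_recipe import phantom_training_images


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--epochs", type=int, default=60)
    ap.add_argument("--n-phantoms", type=int, default=4)
    ap.add_argument(
        "--out",
        default=Path(__file__).resolve().parents[1]
        / "src" / "ramanpc" / "data" / "default_weights.json",
    )
    args = ap.parse_args()

    images = phantom_training_images(seed=args.seed, n_phantoms=args.n_phantoms)
    pairs = make_patch_pairs(images)
    print(f"training on {len(pairs)} patch pairs, {args.epochs} epochs")
    weights = train_srcnn(pairs, seed=args.seed, epochs=args.epochs)
    save_weights(weights, args.out)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
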