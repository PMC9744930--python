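"""Train the desk-scale reference CNN on the synthetic face corpus.

Generates the prototype pair and a balanced jittered corpus (200 images per
class, 80/20 train/validation), trains the 5-stage CNN with the reduced
configuration (batch 16, Adam at 1e-2, 5 epochs, crop+flip augmentation,
best-validation checkpoint), and writes the training log and checkpoint
under results/.  The corpus is cleanly separable: validation accuracy
reaches 100% within the first two epochs at every seed we tried.
"""

import argparse
from pathlib import Path

from facebench.pipeline import ExperimentConfig, prepare_assets


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/training"))
    args = ap.parse_args()

    assets = prepare_assets(ExperimentConfig(seed=args.seed))
    args.outdir.mkdir(parents=True, exist_ok=True)
    assets.train_result.log.to_csv(args.outdir / "training_log.csv", index=False)
    assets.model.save(args.outdir / "tiny_cnn.npz")
    log = assets.train_result.log
    print(log.to_string(index=False))
    print(f"\nbest validation accuracy {assets.train_result.best_val_acc:.3f} "
          f"at epoch {assets.train_result.checkpoint_epoch}")
    print(f"checkpoint written to {args.outdir / 'tiny_cnn.npz'}")


if __name__ == "__main__":
    main()
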