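"""Refit on the packaged training table and freeze the resulting
configuration (grid-searched weights, calibrated thresholds) into
``src/lc8motif/data/config.yaml``.

Run from the repository root:  python scripts/freeze_config.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import yaml

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from lc8motif import MotifBindingClassifier, load_packaged_training
from lc8motif.scoring import PUBLISHED_THRESHOLDS

DATA = Path(__file__).resolve().parents[1] / "src" / "lc8motif" / "data"


def main() -> None:
    training = load_packaged_training()
    X = training.binder_motifs + training.nonbinder_motifs
    y = ["binder"] * len(training.binder_motifs) + ["nonbinder"] * len(training.nonbinder_motifs)
    clf = MotifBindingClassifier().fit(X, y)
    c = clf.confusion_
    cfg = {
        "alpha": clf.alpha,
        "log_base": 2,
        "weight_grid": {"start": 0.0, "stop": 2.0, "step": 0.1},
        "weights": {k: float(v) for k, v in clf.weights_.items()},
        # operating point re-derived on this score scale from the LOO cloud
        "thresholds": {k: float(v) for k, v in clf.thresholds_.items()},
        # operating point printed for the original (unavailable) score scale
        "thresholds_published": PUBLISHED_THRESHOLDS,
        "loo_auc": {"s_aa": round(clf.auc_aa_, 6), "s_vp": round(clf.auc_vp_, 6)},
        "loo_confusion": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
        "anchor_pattern": "[ST]Q[ST]",
        "anchor_pattern_extended": "[STIV][QM][STIV]",
        "disorder_threshold": 0.5,
    }
    header = (
        "# Frozen configuration: combination weights from the LOO ROC grid\n"
        "# search and thresholds calibrated on the LOO score cloud of the\n"
        "# packaged training table.  Regenerate with scripts/freeze_config.py.\n"
    )
    (DATA / "config.yaml").write_text(header + yaml.safe_dump(cfg, sort_keys=False))
    print(f"frozen: weights={cfg['weights']} thresholds={cfg['thresholds']}")


if __name__ == "__main__":
    main()
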