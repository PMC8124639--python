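"""Batch evaluation: per-image metric rows plus an aggregate MEAN row.

The CSV layout mirrors the usual comparison table for enhancement
algorithms: one row per image with columns image, REC, CIR, E, SF, PSNR,
AMBE, and a final MEAN row of unweighted arithmetic means.  Header comment
lines record the metric conventions (contrast reading, clipping mode) so
the numbers stay interpretable; metrics are computed on in-memory arrays,
never on recompressed files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from . import metrics as qm
from .baselines import baseline_enhancer
from .enhance import EnhancementConfig, enhance

__all__ = ["metric_table", "original_table", "batch_enhancer", "write_report"]


def metric_table(
    pairs: Iterable[tuple[str, np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Metric rows for (image id, original, enhanced) triples, plus MEAN."""
    rows = []
    for name, orig, enh in pairs:
        row = {"image": name}
        row.update(qm.evaluate_pair(orig, enh))
        rows.append(row)
    if not rows:
        raise ValueError("no image pairs to evaluate")
    df = pd.DataFrame(rows, columns=["image"] + qm.METRIC_COLUMNS)
    mean = {"image": "MEAN"}
    mean.update({c: df[c].mean() for c in qm.METRIC_COLUMNS})
    return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)


def original_table(images: Iterable[tuple[str, np.ndarray]]) -> pd.DataFrame:
    """Original-image rows: only E and SF are defined without a reference."""
    rows = []
    for name, img in images:
        rows.append(
            {
                "image": name,
                "E": qm.entropy(img),
                "SF": qm.spatial_frequency(img),
            }
        )
    if not rows:
        raise ValueError("no images to evaluate")
    df = pd.DataFrame(rows, columns=["image", "E", "SF"])
    mean = {"image": "MEAN", "E": df["E"].mean(), "SF": df["SF"].mean()}
    return pd.concat([df, pd.DataFrame([mean])], ignore_index=True)


def batch_enhancer(method: str, cfg: EnhancementConfig | None = None) -> Callable:
    """The enhancement callable for a batch method name.

    'msthgr' runs the multi-scale pipeline with ``cfg``; 'he', 'clahe' and
    'gc' dispatch to the comparison baselines.
    """
    method = method.lower()
    if method == "msthgr":
        config = cfg or EnhancementConfig()
        return lambda img: enhance(img, config)
    return baseline_enhancer(method)


def report_header(method: str, cfg: EnhancementConfig | None = None) -> list[str]:
    lines = [
        f"# method: {method}",
        f"# contrast convention: {qm.CONTRAST_CONVENTION}",
        "# metrics computed on in-memory arrays (no recompression)",
    ]
    if cfg is not None:
        clip = "clip-to-[0,255]-and-round" if cfg.clip else "unclipped-real"
        lines.insert(
            1,
            f"# scales n={cfg.n}, se_family={cfg.se_family}, rendering={clip}",
        )
    return lines


def write_report(
    df: pd.DataFrame,
    path,
    method: str = "msthgr",
    cfg: EnhancementConfig | None = None,
) -> None:
    """Write a metric table as CSV with convention-note header lines."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for line in report_header(method, cfg):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.6f")
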