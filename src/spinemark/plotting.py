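"""Diagnostic plots (optional; requires matplotlib).

Two views that matter in practice: the sacral r distribution with its
outlier fence, and the weighted-F1 curve over candidate cutoffs for a
binary task.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .geometry import s1_rotation_screen
from .thresholds import _binary_f1_curve, binarize_labels, candidate_cutoffs


def plot_r_distribution(r_values: Sequence[float], ax=None):
    """Boxplot of sacral r values with the Q3 + 1.5 IQR fence marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(3, 4))
    cutoff, mask = s1_rotation_screen(r_values)
    ax.boxplot(list(r_values), whis=1.5)
    ax.axhline(cutoff, color="crimson", ls="--",
               label=f"fence = {cutoff:.4f} ({int(mask.sum())} pass)")
    ax.set_ylabel("sacral rotation r")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_f1_curve(magnitudes: Sequence[float], labels: Sequence[str],
                  malposition_type: str = "coronal", ax=None,
                  cutoff: Optional[float] = None):
    """Weighted F1 versus cutoff for a binary magnitude task."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 3))
    m = np.abs(np.asarray(magnitudes, dtype=float))
    binary = binarize_labels(list(labels), malposition_type)
    cand = candidate_cutoffs(m)
    cand = np.concatenate([[0.0], cand[cand > 0]])
    curve = _binary_f1_curve(m, binary == "malposition", cand)
    ax.step(cand, curve, where="post")
    if cutoff is not None:
        ax.axvline(cutoff, color="crimson", ls="--", label=f"cutoff {cutoff:.2f}")
        ax.legend(fontsize=8)
    ax.set_xlabel("cutoff (degrees)")
    ax.set_ylabel("weighted F1")
    ax.set_ylim(0, 1.02)
    return ax
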