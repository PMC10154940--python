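"""Debugging plot: overlay of coarse vs fine Fourier reconstructions."""

from __future__ import annotations

from .complexity import complexity_score
from .efa import compute_efa, reconstruct
from .outlines import Outline


def plot_reconstruction_overlay(outline: Outline, h_low: int = 8,
                                h_high: int = 1000, ax=None):
    """Overlay the h_low and h_high reconstructions of one outline.

    The congruent region shows as the overlap of the two filled curves, the
    non-congruent region as the fringes covered by only one — the visual
    counterpart of the complexity score, which is annotated on the axes.
    Returns the matplotlib axes.  Debugging aid only.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    n_fit = max(4096, len(outline))
    efa = compute_efa(outline, min(h_high, n_fit // 2), n_points_fit=n_fit,
                      parameterization="uniform")
    lo = reconstruct(efa, h_low, 2048)
    hi = reconstruct(efa, efa.n_max, 2048)
    ax.fill(hi.points[:, 0], hi.points[:, 1], color="tab:red", alpha=0.45,
            label=f"{efa.n_max} harmonics")
    ax.fill(lo.points[:, 0], lo.points[:, 1], color="tab:blue", alpha=0.45,
            label=f"{h_low} harmonics")
    score = complexity_score(outline, h_low=h_low, h_high=h_high)
    ax.set_title(f"complexity = {score.value:.3f}")
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: y down
    ax.legend(loc="best", fontsize="small")
    return ax
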