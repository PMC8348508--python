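"""Plot writers for the standard model-diagnostic figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_fit(y_obs, y_pred, path, sets=None) -> None:
    """Experimental vs predicted response with the identity line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    if sets is None:
        ax.scatter(y_obs, y_pred, s=12, alpha=0.7)
    else:
        import numpy as np

        sets = np.asarray(sets)
        for label, marker in (("train", "o"), ("external", "^")):
            mask = sets == label
            ax.scatter(
                np.asarray(y_obs)[mask], np.asarray(y_pred)[mask],
                s=14, alpha=0.7, marker=marker, label=label,
            )
        ax.legend()
    lo = min(min(y_obs), min(y_pred))
    hi = max(max(y_obs), max(y_pred))
    ax.plot([lo, hi], [lo, hi], "k-", lw=1)
    ax.set_xlabel("experimental pKi")
    ax.set_ylabel("predicted pKi")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_williams(ad_table, h_star, resid_cut, path) -> None:
    """Leverage vs standardized residual with h* and residual boundaries."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for label, marker in (("train", "o"), ("external", "^")):
        sub = ad_table[ad_table["set"] == label]
        if len(sub):
            ax.scatter(sub["leverage"], sub["std_residual"], s=14, alpha=0.7,
                       marker=marker, label=label)
    ax.axvline(h_star, color="k", lw=1)
    ax.axhline(resid_cut, color="k", ls="--", lw=1)
    ax.axhline(-resid_cut, color="k", ls="--", lw=1)
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_yscramble(yscr_table, kxy_unscrambled, r2_real, q2_real, path) -> None:
    """Kxy vs R2/Q2 for scrambled responses, with the real model marked."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(yscr_table["kxy"], yscr_table["r2_scr"], s=10, alpha=0.5,
               label="R2 (scrambled)")
    ax.scatter(yscr_table["kxy"], yscr_table["q2_scr"], s=10, alpha=0.5,
               label="Q2 (scrambled)")
    ax.scatter([kxy_unscrambled], [r2_real], marker="*", s=120, color="tab:red",
               label="real model R2")
    ax.scatter([kxy_unscrambled], [q2_real], marker="*", s=120, color="tab:green",
               label="real model Q2")
    ax.set_xlabel("Kxy")
    ax.set_ylabel("R2 / Q2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_selection_curve(scores, breaking_m, path) -> None:
    """R2_tr and Q2_LOO against model size, marking the breaking point."""
    ms = [s[0] for s in scores]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ms, [s[1] for s in scores], "o-", label="R2_tr")
    ax.plot(ms, [s[2] for s in scores], "s-", label="Q2_LOO")
    ax.axvline(breaking_m, color="k", ls=":", lw=1)
    ax.set_xlabel("number of descriptors")
    ax.set_ylabel("R2 / Q2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
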