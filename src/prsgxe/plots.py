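"""Figure-style outputs: association by threshold, and interaction plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_association_by_threshold(assoc: pd.DataFrame, path) -> None:
    """Bar chart of the partial correlation at each p-value threshold."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar([f"{t:g}" for t in assoc["threshold"]], assoc["partial_r"],
           color="#4477aa")
    ax.set_xlabel("discovery p-value threshold")
    ax.set_ylabel("partial r (controlling for sex)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_interaction(predicted: pd.DataFrame, environment: str, path) -> None:
    """Predicted outcome at +/-1 SD of score, by environment level.

    The riskier (high) environment level is placed on the right; error
    bars are the stored residual-SD / sqrt(n) values.
    """
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    for s_level, color in (("low", "#999933"), ("high", "#882255")):
        sub = predicted[predicted["score_level"] == s_level]
        sub = sub.set_index("env_level").loc[["low", "high"]]
        ax.errorbar([0, 1], sub["predicted"], yerr=sub["error_bar"],
                    marker="o", color=color, capsize=3,
                    label=f"{s_level} polygenic score")
    ax.set_xticks([0, 1], ["low risk", "high risk"])
    ax.set_xlabel(environment.replace("_", " "))
    ax.set_ylabel("predicted alcohol problems")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
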