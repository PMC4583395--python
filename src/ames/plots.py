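"""Figure output for the report verb: response curves and learning curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .simulate import SESSION_RATIOS
from .templates import make_template, template_profile


def plot_response_curves(curves: pd.DataFrame, out_path: str | Path) -> None:
    """Group mean curves, pre vs post, with the template overlay per session."""
    groups = sorted(curves["group"].unique())
    sessions = sorted(curves["session"].unique())
    fig, axes = plt.subplots(
        len(sessions), len(groups), figsize=(4.2 * len(groups), 3.2 * len(sessions)),
        squeeze=False,
    )
    for i, session in enumerate(sessions):
        template = make_template(4.0, 1.0, SESSION_RATIOS[session])
        for j, group in enumerate(groups):
            ax = axes[i][j]
            sel = curves[
                (curves["level"] == "group")
                & (curves["group"] == group)
                & (curves["session"] == session)
            ]
            for phase, color in [("pre_test", "tab:red"), ("post_test", "tab:blue")]:
                ph = sel[sel["phase"] == phase].sort_values("grid")
                if not ph.empty:
                    ax.plot(ph["grid"], ph["fitted"], color=color, label=phase)
            n = sel["grid"].nunique() or 50
            prof = template_profile(template, n)
            ax.plot([k / (n - 1) for k in range(n)], prof, "k--", lw=1, label="template")
            ax.set_title(f"{group} / {session}", fontsize=9)
            ax.set_xlabel("normalized time")
            ax.set_ylabel("rescaled displacement")
            if i == 0 and j == 0:
                ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_learning_curves(learning: pd.DataFrame, out_path: str | Path) -> None:
    """Trial-wise group-mean magnitude error, one panel per session."""
    sessions = sorted(learning["session"].unique())
    fig, axes = plt.subplots(1, len(sessions), figsize=(4.5 * len(sessions), 3.2), squeeze=False)
    for i, session in enumerate(sessions):
        ax = axes[0][i]
        for group, color in [("concurrent_vf", "tab:green"), ("post_trial_vf", "tab:orange")]:
            cell = learning[
                (learning["group"] == group) & (learning["session"] == session)
            ].sort_values("trial")
            if not cell.empty:
                ax.plot(cell["trial"], cell["mean_magnitude_error_mm"], "o-", color=color,
                        label=group)
        ax.set_title(f"session: {session}", fontsize=9)
        ax.set_xlabel("training trial")
        ax.set_ylabel("magnitude error (mm)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
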