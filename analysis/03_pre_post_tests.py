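"""Within-group pre/post comparisons of the two error measures.

For every group x session x metric cell, the per-participant pre- and
post-test means are compared with the normality-routed paired test:
Shapiro-Wilk on the differences decides between the paired t-test and
the Wilcoxon signed-rank test at alpha = 0.05. Prints the machine-readable
results table written by the scoring step and flags the significant
reductions.
"""

from pathlib import Path

import pandas as pd

TABLES = Path(__file__).resolve().parents[1] / "results" / "tables"

if __name__ == "__main__":
    tests = pd.read_csv(TABLES / "test_results.csv")
    print(tests.to_string(index=False))
    sig = tests[tests.significant & (tests.direction > 0)]
    print(f"\n{len(sig)}/{len(tests)} cells show a significant pre->post error reduction:")
    for _, r in sig.iterrows():
        print(f"  {r.group} / {r.session} / {r.metric}: "
              f"{r.test_used} p={r.p_value:.4g}")
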