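"""Motion-pattern response curves: pre vs post, against the template.

Plots the group mean response curves (penalized-spline smooths of the
rescaled motion units, averaged over participants) with the session
template overlaid, and reports the grid-mean squared distance of each
group curve to its template — the qualitative claim being that training
moves the complicated-session curves toward the 2:1 template.
"""

from pathlib import Path

import pandas as pd

from ames import complicated_template, simple_template
from ames.curves import ResponseCurve, curve_template_distance
from ames.plots import plot_response_curves

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    curves = pd.read_csv(ROOT / "tables" / "response_curves.csv")
    plot_response_curves(curves, ROOT / "response_curves.png")
    templates = {"simple": simple_template(), "complicated": complicated_template()}
    print("grid-mean squared distance of group curves to the session template:")
    for (group, session, phase), sel in curves[curves.level == "group"].groupby(
        ["group", "session", "phase"]
    ):
        sel = sel.sort_values("grid")
        c = ResponseCurve(sel.grid.to_numpy(), sel.fitted.to_numpy(), "group")
        d = curve_template_distance(c, templates[session])
        print(f"  {group:15s} {session:12s} {phase:9s}: {d:.5f}")
    print(f"figure: {ROOT / 'response_curves.png'}")
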