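#!/usr/bin/env python
"""Solve the four index-selection scenarios on the synthetic panel.

Evaluates S1 and S2 plus their refinements — S1* additionally holds
moisture content unchanged, S2* holds flowering time unchanged — and
writes per-scenario reports (weights, implied economic values and their
ratios, all 16 correlated responses, intensity and selected fraction) and
a side-by-side comparison flagging responses that switch sign between
scenarios.

Reads the inputs written by 01_build_panel.py; outputs under
results/scenarios/.
"""

from pathlib import Path

from gainsel import GeneticParameters, compare_scenarios, refine_scenario, run_scenario
from gainsel import io as gio
from gainsel.engine import format_ratio

ROOT = Path(__file__).resolve().parent.parent / "results"
IN = ROOT / "synthetic"
OUT = ROOT / "scenarios"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel, _ = gio.read_panel(IN / "panel.csv")
    params = GeneticParameters(G=gio.read_matrix(IN / "G.csv", panel),
                               P=gio.read_matrix(IN / "P.csv", panel))
    s1 = gio.read_scenario(IN / "S1.yaml")
    s2 = gio.read_scenario(IN / "S2.yaml")
    scenarios = [
        s1,
        s2,
        refine_scenario(s1, ["Moisture.9"]),
        refine_scenario(s2, ["DOYFS1.9"]),
    ]

    reports = []
    for scenario in scenarios:
        rep = run_scenario(panel, params, scenario)
        gio.write_report(rep, OUT)
        reports.append(rep)
        sol = rep.solution
        gained = [panel.names[j] for j in rep.mask]
        ratios = rep.table.set_index("trait")["econ_ratio"]
        ratio_str = ":".join(format_ratio(float(ratios[t])) for t in gained)
        print(f"{scenario.name}: i = {sol.i:.2f} (top {100 * sol.p:.3g} % kept); "
              f"econ ratios {':'.join(gained)} = {ratio_str}")

    table = compare_scenarios(*reports)
    table.to_csv(OUT / "comparison.csv", index=False)
    flips = table.loc[table["sign_flip"], "trait"].tolist()
    print(f"responses switching sign across scenarios: {flips or 'none'}")
    print(f"wrote reports and comparison under {OUT}")


if __name__ == "__main__":
    main()
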