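#!/usr/bin/env python
"""Build the synthetic 16-trait evaluation panel and its covariance matrices.

Writes the trait panel (names, units, current means, heritabilities), the
assembled genetic (G) and phenotypic (P) covariance matrices, and the two
baseline breeding scenarios:

* S1 — raise dry biomass yield 20 % of the current mean and delay
  flowering by 44 days (~20 %).
* S2 — raise yield 20 %, raise cellulose 5 % and cut lignin 5 % of their
  current means, leaving phenology free.

Outputs under results/synthetic/ in the delimited formats the solver reads.
"""

from pathlib import Path

import numpy as np

from gainsel import Gain, Scenario, build_covariances, default_panel
from gainsel import io as gio

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel, spec = default_panel()
    params = build_covariances(spec)

    gio.write_panel(panel, OUT / "panel.csv", h2=spec.h2)
    gio.write_matrix(params.G, panel, OUT / "G.csv")
    gio.write_matrix(params.P, panel, OUT / "P.csv")

    s1 = Scenario("S1", [Gain("DryMatter.9", 20.0, "percent"),
                         Gain("DOYFS1.9", 44.0, "absolute")])
    s2 = Scenario("S2", [Gain("DryMatter.9", 20.0, "percent"),
                         Gain("Cellulose.8", 5.0, "percent"),
                         Gain("Lignin.8", -5.0, "percent")])
    gio.write_scenario(s1, OUT / "S1.yaml")
    gio.write_scenario(s2, OUT / "S2.yaml")

    d = np.sqrt(np.diag(params.G))
    r = params.G / np.outer(d, d)
    i, j, k, m = (panel.index_of(t) for t in
                  ("DOYFS1.9", "DryMatter.9", "Moisture.9", "AvgeSen.9"))
    print(f"panel: {panel.n} traits, h2 in [{spec.h2.min():.2f}, {spec.h2.max():.2f}]")
    print(f"genetic correlations: flowering-yield {r[i, j]:.2f}, "
          f"flowering-moisture {r[i, k]:.2f}, flowering-senescence {r[i, m]:.2f}")
    print(f"G min eigenvalue {np.linalg.eigvalsh(params.G).min():.4g} (PSD), "
          f"E min eigenvalue {np.linalg.eigvalsh(params.E).min():.4g}")
    print(f"wrote panel, G, P, S1, S2 under {OUT}")


if __name__ == "__main__":
    main()
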