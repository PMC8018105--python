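"""Morphology-score inference from published group summaries.

The histomorphology comparison uses only per-group summary statistics
(mean, SEM, n) as inputs: Ki67 proliferation index 11.62 +/- 2.83 for 14
primary vs 26.05 +/- 3.16 for 25 relapsed samples, and cell density
2 +/- 0.25 vs 2.76 +/- 0.10 on the 1-3 ordinal scale. A pooled-variance
unpaired t is reconstructed from each summary pair; Welch is reported
alongside.
"""

from pathlib import Path

import pandas as pd

from epirelapse.morphology import t_from_summary

ROOT = Path(__file__).resolve().parents[1]

# variable -> (mean, sem, n) per group, as published
SUMMARIES = {
    "ki67": {"PRIMARY": (11.62, 2.83, 14), "RELAPSE": (26.05, 3.16, 25)},
    "cell_density": {"PRIMARY": (2.0, 0.25, 14), "RELAPSE": (2.76, 0.10, 25)},
}


def main() -> None:
    rows = []
    for var, groups in SUMMARIES.items():
        (m1, s1, n1), (m2, s2, n2) = groups["PRIMARY"], groups["RELAPSE"]
        for mode in ("student_pooled", "welch"):
            t, df, p = t_from_summary(m1, s1, n1, m2, s2, n2, mode)
            rows.append(dict(variable=var, mode=mode, mean_primary=m1,
                             mean_relapse=m2, t_stat=t, df=df, p_value=p))
    table = pd.DataFrame(rows)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "05_morphology_tests.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print(table.round(4).to_string(index=False))
    print(
        "\nboth variables increase at relapse; the pooled Ki67 p (0.0043)"
        "\nreproduces the published comparison from its summaries alone."
        "\nthe pooled cell-density p (0.0020) lands near but not exactly on"
        "\nthe published 0.0018 — the per-sample scores are unpublished and"
        "\nthe group sizes here are assumed equal to the Ki67 ones, so the"
        "\nresidual gap is expected"
    )


if __name__ == "__main__":
    main()
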