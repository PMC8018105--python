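"""Paired probe-level differential methylation, cohort and per subgroup.

Re-draws the seed-1 cohort from 01, converts betas to M-values, forms one
(primary, relapse) pair per patient and runs the per-probe paired t with
Benjamini-Hochberg adjustment — once over all 45 pairs and once within
each molecular subgroup, including the n=2 subgroups (df = 1). Writes a
per-scope significance summary to results/ and full probe tables to
scratch/.
"""

from pathlib import Path

import pandas as pd

from epirelapse.diffmeth import run_dmp
from epirelapse.io_model import align_inputs
from epirelapse.synthetic import SimulationConfig, simulate_dataset

SEED = 1
ALPHA = 0.05
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ds = simulate_dataset(SimulationConfig(n_probes=20_000, seed=SEED))
    al = align_inputs(ds.annotation, ds.beta, ds.sheet)

    tables = {"cohort": run_dmp(al)}
    tables.update(run_dmp(al, "per_subgroup"))

    scratch = ROOT / "scratch" / "dmp"
    scratch.mkdir(parents=True, exist_ok=True)
    rows = []
    for scope, tab in tables.items():
        t = tab.table
        t.to_csv(scratch / f"dmp_{scope}.tsv", sep="\t", float_format="%.6g")
        rows.append(
            dict(
                scope=scope,
                n_pairs=int(t["n_pairs"].max()) if len(t) else 0,
                n_tested=int(t["p_raw"].notna().sum()) if len(t) else 0,
                n_sig_raw=int((t["p_raw"] < ALPHA).sum()) if len(t) else 0,
                n_sig_bh=int((t["p_adj"] < ALPHA).sum()) if len(t) else 0,
            )
        )
    summary = pd.DataFrame(rows)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    summary.to_csv(out / "02_dmp_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        "\nplanted island/shelf shifts drive the cohort and the three large"
        "\nsubgroups; the n=2 subgroups (df = 1 per probe) retain almost no"
        "\npower, mirroring how tiny subgroups behave in paired designs"
    )


if __name__ == "__main__":
    main()
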