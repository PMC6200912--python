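"""Reference ROF table and its arithmetic self-check.

The package ships a transcription of the published per-acquisition ROF
table for the three patients (EMCS, MCS, UWS) across the nine networks.
``check_rof_table`` recomputes every delta-ROF from the two ROF columns
(missing acquisition -> 0) and the per-patient mean |delta-ROF|, and
reports agreement at the table's 2-decimal precision.

Published summary values reproduced by the check:

* mean |delta-ROF|: EMCS 0.32, MCS 0.26, UWS 0.39
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError
from .rof import delta_rof, mean_abs_delta_rof

REFERENCE_COLUMNS = ("patient", "network", "in_t1", "out_t1", "rof_t1",
                     "in_t2", "out_t2", "rof_t2", "delta_rof")

#: Published per-patient mean |delta-ROF| values.
REFERENCE_MEANS = {"EMCS": 0.32, "MCS": 0.26, "UWS": 0.39}


@dataclass
class TableCheck:
    """Outcome of recomputing a ROF table's derived columns."""

    n_cells: int
    n_matching: int
    mismatches: list[dict] = field(default_factory=list)
    recomputed_delta: dict[tuple[str, str], float] = field(default_factory=dict)
    recomputed_means: dict[str, float] = field(default_factory=dict)
    mean_mismatches: list[dict] = field(default_factory=list)

    @property
    def all_match(self) -> bool:
        return not self.mismatches and not self.mean_mismatches


def load_reference_table() -> pd.DataFrame:
    """The packaged reference ROF table as a DataFrame."""
    with resources.files("rsnvar.data").joinpath(
            "rof_reference.tsv").open("r") as fh:
        return read_rof_table(fh)


def read_rof_table(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t")
    if df.empty:
        raise ValidationError("ROF table is empty")
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"ROF table missing column(s) {missing}")
    return df


def check_rof_table(df: pd.DataFrame,
                    expected_means: dict[str, float] | None = None,
                    decimals: int = 2) -> TableCheck:
    """Recompute delta-ROF and mean |delta-ROF| and compare to the table.

    A blank printed delta-ROF is expected to equal 0 under the
    missing-as-zero convention (doubly-missing networks).
    """
    check = TableCheck(n_cells=0, n_matching=0)
    for _, row in df.iterrows():
        r1 = None if pd.isna(row["rof_t1"]) else float(row["rof_t1"])
        r2 = None if pd.isna(row["rof_t2"]) else float(row["rof_t2"])
        computed = round(delta_rof(r1, r2), decimals)
        printed = (0.0 if pd.isna(row["delta_rof"])
                   else float(row["delta_rof"]))
        key = (str(row["patient"]), str(row["network"]))
        check.recomputed_delta[key] = computed
        check.n_cells += 1
        if abs(computed - printed) < 10 ** (-decimals) / 2:
            check.n_matching += 1
        else:
            check.mismatches.append({
                "patient": key[0], "network": key[1],
                "printed": printed, "recomputed": computed,
            })

    if expected_means is None:
        expected_means = {}
    for patient, grp in df.groupby("patient", sort=False):
        deltas = [check.recomputed_delta[(str(patient), str(n))]
                  for n in grp["network"]]
        mean = round(mean_abs_delta_rof(deltas, n_networks=len(deltas)),
                     decimals)
        check.recomputed_means[str(patient)] = mean
        expected = expected_means.get(str(patient))
        if expected is not None and abs(mean - expected) >= \
                10 ** (-decimals) / 2:
            check.mean_mismatches.append({
                "patient": str(patient), "expected": expected,
                "recomputed": mean,
            })
    return check
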