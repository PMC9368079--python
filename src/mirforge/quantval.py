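"""Relative expression by the 2^-ddCt method for qRT-PCR validation.

Per sample, dCt = Ct(target) - Ct(reference gene); per group, ddCt is
the group-mean dCt minus the control-group-mean dCt, and the fold
change is 2^-ddCt (control fold identically 1).  Group summaries use
the arithmetic mean of per-sample dCt; per-sample folds are emitted
alongside so callers can attach standard errors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["sample", "group", "gene", "reference", "ct"]


class CtTableError(ValueError):
    pass


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CtTableError(f"Ct table lacks columns: {missing}")
    if (table["ct"] <= 0).any():
        bad = table.loc[table["ct"] <= 0, "sample"].tolist()
        raise CtTableError(f"non-positive Ct values for samples: {bad}")
    return table


def delta_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample dCt for every non-reference assay row."""
    table = _validate(table)
    ref_ct = {(r["sample"], r["gene"]): r["ct"]
              for _, r in table.iterrows()}
    rows = []
    for _, r in table.iterrows():
        if r["gene"] == r["reference"]:
            continue
        key = (r["sample"], r["reference"])
        if key not in ref_ct:
            raise CtTableError(
                f"missing reference {r['reference']!r} measurement for "
                f"sample {r['sample']!r}")
        rows.append(dict(sample=r["sample"], group=r["group"], gene=r["gene"],
                         dct=r["ct"] - ref_ct[key]))
    return pd.DataFrame(rows)


def ddct_fold_change(
    table: pd.DataFrame, control: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-group 2^-ddCt fold changes relative to ``control``.

    Returns (group-level folds, per-sample folds).  The group table
    carries gene, group, n, ddct, fold and log2 fold; the control group's
    fold is 1 by construction.
    """
    dct = delta_ct(table)
    if control not in set(dct["group"]):
        raise CtTableError(f"control group {control!r} absent from table")
    group_rows, sample_rows = [], []
    for gene, sub in dct.groupby("gene", sort=True):
        ctrl = sub.loc[sub["group"] == control, "dct"]
        if ctrl.empty:
            raise CtTableError(f"gene {gene!r} has no control-group samples")
        ctrl_mean = float(ctrl.mean())
        for group, gsub in sub.groupby("group", sort=True):
            ddct = float(gsub["dct"].mean()) - ctrl_mean
            group_rows.append(dict(
                gene=gene, group=group, n=len(gsub), ddct=ddct,
                fold=2.0 ** (-ddct), log2_fold=-ddct))
        for _, r in sub.iterrows():
            sd = r["dct"] - ctrl_mean
            sample_rows.append(dict(sample=r["sample"], group=r["group"],
                                    gene=gene, fold=2.0 ** (-sd)))
    groups = pd.DataFrame(group_rows)
    samples = pd.DataFrame(sample_rows)
    return groups, samples
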