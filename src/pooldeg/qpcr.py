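"""2^-ddCt relative quantification and direction agreement with DE calls.

Relative expression of a target gene in the test group versus a
calibrator group, normalized to a housekeeping gene (EIF5A in the study
design this package targets): per sample, dCt = Ct_target -
Ct_housekeeping; ddCt = mean dCt(test) - mean dCt(calibrator); relative
expression = 2^-ddCt.  Replicate-level values take each test sample's
dCt against the calibrator group mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DEResult, InputError

__all__ = ["RelativeExpression", "delta_delta_ct", "direction_agreement"]


@dataclass
class RelativeExpression:
    """Per-gene 2^-ddCt values for the test group vs the calibrator."""

    test_group: str
    calibrator_group: str
    housekeeping_gene: str
    table: pd.DataFrame  # gene, rel_expr, sd, direction
    replicate_values: dict[str, np.ndarray]


def _sample_dct(table: pd.DataFrame, housekeeping_gene: str) -> pd.DataFrame:
    """Mean dCt per (sample, gene), averaging technical replicates."""
    ct = table.groupby(["sample", "group", "gene"], sort=False)["ct"].mean().reset_index()
    hk = ct[ct["gene"] == housekeeping_gene].set_index("sample")["ct"]
    missing = sorted(set(ct["sample"]) - set(hk.index))
    if missing:
        raise InputError(f"samples missing housekeeping gene {housekeeping_gene!r}: "
                         f"{missing}")
    targets = ct[ct["gene"] != housekeeping_gene].copy()
    targets["dct"] = targets["ct"].to_numpy() - hk.loc[targets["sample"]].to_numpy()
    return targets


def delta_delta_ct(table: pd.DataFrame, housekeeping_gene: str = "EIF5A",
                   calibrator_group: str = "low",
                   flat_threshold: float = 0.1) -> RelativeExpression:
    """Group-mean-calibrated 2^-ddCt relative expression.

    ``table`` has columns sample, group, gene, ct (and optionally
    replicate for technical replicates, which are averaged per sample).
    Direction is up/down when |log2 relative expression| >=
    ``flat_threshold``, else flat.
    """
    for col in ("sample", "group", "gene", "ct"):
        if col not in table.columns:
            raise InputError(f"Ct table missing column {col!r}")
    groups = list(pd.unique(table["group"]))
    if calibrator_group not in groups:
        raise InputError(f"calibrator group {calibrator_group!r} absent from table")
    others = [g for g in groups if g != calibrator_group]
    if len(others) != 1:
        raise InputError("Ct table must contain exactly two groups")
    test_group = others[0]

    dct = _sample_dct(table, housekeeping_gene)
    rows, rep_values = [], {}
    for gene, sub in dct.groupby("gene", sort=False):
        cal = sub[sub["group"] == calibrator_group]["dct"].to_numpy()
        test = sub[sub["group"] == test_group]["dct"].to_numpy()
        if cal.size == 0 or test.size == 0:
            raise InputError(f"gene {gene!r} missing in one of the groups")
        ddct = test.mean() - cal.mean()
        rel = float(2.0 ** (-ddct))
        reps = 2.0 ** (-(test - cal.mean()))
        log2rel = -ddct
        direction = ("flat" if abs(log2rel) < flat_threshold
                     else "up" if log2rel > 0 else "down")
        rows.append({"gene": gene, "rel_expr": rel,
                     "sd": float(reps.std(ddof=1)) if reps.size > 1 else 0.0,
                     "direction": direction})
        rep_values[gene] = reps
    return RelativeExpression(
        test_group=test_group, calibrator_group=calibrator_group,
        housekeeping_gene=housekeeping_gene,
        table=pd.DataFrame(rows, columns=["gene", "rel_expr", "sd", "direction"]),
        replicate_values=rep_values,
    )


def direction_agreement(rel: RelativeExpression, de: DEResult) -> pd.DataFrame:
    """Does the qPCR direction match the RNA-seq log2FC sign, per gene?

    Returns a frame (gene, rel_expr, log2_rel, de_log2fc, agree) with a
    ``fraction_agree`` value in ``frame.attrs``.  Agreement is sign
    equality of log2 relative expression and DE log2FC.
    """
    de_tab = de.table.set_index("gene_id")
    shared = [g for g in rel.table["gene"] if g in de_tab.index]
    if not shared:
        raise InputError("no genes shared between qPCR table and DE result")
    rel_tab = rel.table.set_index("gene").loc[shared]
    log2rel = np.log2(rel_tab["rel_expr"].to_numpy())
    lfc = de_tab.loc[shared, "log2FC"].to_numpy()
    agree = np.sign(log2rel) == np.sign(lfc)
    out = pd.DataFrame({
        "gene": shared,
        "rel_expr": rel_tab["rel_expr"].to_numpy(),
        "log2_rel": log2rel,
        "de_log2fc": lfc,
        "agree": agree,
    })
    out.attrs["fraction_agree"] = float(agree.mean())
    return out
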