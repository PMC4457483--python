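"""Decision-tree biomarker validation and cross-tissue / cross-modality checks.

A metabolite first has to be significant in the high-dose contrast
(50 Gy vs 0 Gy sham) and is then *confirmed* by a second, independent
contrast: 50 Gy vs untreated with the same direction, or failing that one of
the low-dose contrasts (10 Gy vs 0 Gy, 10 Gy vs untreated).  Metabolites
significant at only one dose level with no confirming contrast are flagged
unconfirmed (the "YY" case); those can still be rescued by significance in
the whole-body-irradiation companion study, whose effect direction relative
to whole-liver irradiation is recorded as concordant or opposite.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARISONS = ("50Gy_vs_0Gy", "50Gy_vs_untreated", "10Gy_vs_0Gy", "10Gy_vs_untreated")
C50_0, C50_U, C10_0, C10_U = COMPARISONS
WBI_COMPARISON = "10Gy_vs_0Gy"

STATUS_PRIMARY_CONFIRMED = "validated_primary_confirmed"
STATUS_PRIMARY = "validated_primary"
STATUS_LOW_DOSE = "validated_low_dose"
STATUS_UNCONFIRMED = "single_level_unconfirmed"
STATUS_NOT_SIG = "not_significant"

MODALITY_WLI_ONLY = "wli_only"
MODALITY_WBI_ONLY = "wbi_only"
MODALITY_SAME = "shared_same_direction"
MODALITY_OPPOSITE = "shared_opposite_direction"
MODALITY_NA = "n/a"


def _pivot(stats: pd.DataFrame, comparisons: tuple[str, ...]) -> pd.DataFrame:
    """Wide per-metabolite view with sig_/dir_/q_/ratio_ columns per comparison."""
    missing = [c for c in comparisons if c not in set(stats["comparison"])]
    if missing:
        raise ValueError(f"missing comparison(s) in stats input: {missing}")
    sub = stats[stats["comparison"].isin(comparisons)]
    wide = sub.pivot(index="metabolite", columns="comparison",
                     values=["significant", "direction", "q", "ratio"])
    out = pd.DataFrame(index=wide.index)
    for c in comparisons:
        out[f"sig_{c}"] = wide[("significant", c)].eq(True)
        out[f"dir_{c}"] = wide[("direction", c)]
        out[f"q_{c}"] = wide[("q", c)]
        out[f"ratio_{c}"] = wide[("ratio", c)]
    return out.sort_index()


def _classify_row(r: pd.Series) -> tuple[str, list[str]]:
    sig = {c: bool(r[f"sig_{c}"]) for c in COMPARISONS}
    dirn = {c: r[f"dir_{c}"] for c in COMPARISONS}

    low_sig = [c for c in (C10_0, C10_U) if sig[c]]
    low_consistent = len(low_sig) != 2 or dirn[C10_0] == dirn[C10_U]

    if sig[C50_0] and sig[C50_U] and dirn[C50_0] == dirn[C50_U]:
        confirming = [C50_0, C50_U]
        # low-dose agreement is recorded on top of the primary confirmation
        confirming += [c for c in low_sig if dirn[c] == dirn[C50_0]]
        return STATUS_PRIMARY_CONFIRMED, confirming
    if sig[C50_0] and low_sig and low_consistent:
        same_dir = [c for c in low_sig if dirn[c] == dirn[C50_0]]
        if same_dir:
            return STATUS_PRIMARY, [C50_0, *same_dir]
    if not sig[C50_0] and len(low_sig) == 2 and low_consistent:
        return STATUS_LOW_DOSE, low_sig
    if any(sig.values()):
        return STATUS_UNCONFIRMED, []
    return STATUS_NOT_SIG, []


def run_cascade(stats: pd.DataFrame, tissue: str | None = None) -> pd.DataFrame:
    """Apply the decision tree to one tissue/modality's univariate results.

    ``stats`` is the long output of :func:`radmetab.stats.run_comparisons`
    containing all four cascade comparisons.  Returns one row per metabolite
    with cascade_status, the confirming comparisons (joined by ';'), the
    minimum q over confirming comparisons, and per-comparison significance,
    direction, q and ratio columns.  Output is ordered by metabolite id, so
    it does not depend on input row order.
    """
    if tissue is None and "tissue" in stats.columns and len(stats):
        tissue = stats["tissue"].iloc[0]
    wide = _pivot(stats, COMPARISONS)
    statuses, confirmings, min_q = [], [], []
    for _, row in wide.iterrows():
        status, confirming = _classify_row(row)
        statuses.append(status)
        confirmings.append(";".join(confirming))
        min_q.append(min((row[f"q_{c}"] for c in confirming), default=np.nan))
    wide.insert(0, "tissue", tissue)
    wide.insert(1, "cascade_status", statuses)
    wide.insert(2, "confirming_comparisons", confirmings)
    wide.insert(3, "min_q", min_q)
    wide.insert(4, "cross_tissue", False)
    wide.insert(5, "cross_modality", MODALITY_NA)
    counts = wide["cascade_status"].value_counts().to_dict()
    logger.info("cascade (%s): %s", tissue, counts)
    return wide.reset_index()


def cross_tissue_validate(
    liver: pd.DataFrame, plasma: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flag metabolites carried by the cascade in BOTH liver and plasma.

    Returns updated (liver, plasma) record tables plus the cross-tissue
    biomarker panel, sorted by the smaller of the two tissues' minimum
    confirming q-values (most confident first).
    """
    lv = liver.set_index("metabolite")
    pl = plasma.set_index("metabolite")
    shared = lv.index.intersection(pl.index)
    hit = [
        m
        for m in shared
        if lv.at[m, "cascade_status"] != STATUS_NOT_SIG
        and pl.at[m, "cascade_status"] != STATUS_NOT_SIG
    ]
    lv.loc[hit, "cross_tissue"] = True
    pl.loc[hit, "cross_tissue"] = True
    panel = pd.DataFrame(
        {
            "metabolite": hit,
            "liver_status": lv.loc[hit, "cascade_status"].to_numpy(),
            "plasma_status": pl.loc[hit, "cascade_status"].to_numpy(),
            "min_q": np.fmin(lv.loc[hit, "min_q"].to_numpy(), pl.loc[hit, "min_q"].to_numpy()),
        }
    ).sort_values(["min_q", "metabolite"], na_position="last", kind="stable")
    logger.info("cross-tissue panel: %d of %d shared metabolites", len(hit), len(shared))
    return lv.reset_index(), pl.reset_index(), panel.reset_index(drop=True)


def cross_modality_validate(wli_records: pd.DataFrame, wbi_stats: pd.DataFrame) -> pd.DataFrame:
    """Annotate WLI cascade records with the whole-body companion evidence.

    ``wbi_stats`` is the long univariate output for the WBI cohort and must
    contain the 10 Gy vs 0 Gy comparison (the only contrast that modality
    supports).  Metabolites stuck at single_level_unconfirmed that are
    significant in WBI are upgraded to validated_low_dose; direction
    concordance between the WLI and WBI 10 Gy responses is labeled by which
    side of 1 the two fold-change ratios fall on.
    """
    wbi = wbi_stats[wbi_stats["comparison"] == WBI_COMPARISON].set_index("metabolite")
    if wbi.empty:
        raise ValueError(f"WBI stats lack the {WBI_COMPARISON} comparison")
    rec = wli_records.set_index("metabolite").copy()
    upgraded = 0
    for m in rec.index:
        wli_sig = bool(rec.at[m, f"sig_{C10_0}"])
        wli_ratio = rec.at[m, f"ratio_{C10_0}"]
        in_wbi = m in wbi.index
        wbi_sig = bool(wbi.at[m, "significant"]) if in_wbi else False
        wbi_ratio = wbi.at[m, "ratio"] if in_wbi else np.nan

        if rec.at[m, "cascade_status"] == STATUS_UNCONFIRMED and wbi_sig:
            rec.at[m, "cascade_status"] = STATUS_LOW_DOSE
            confirming = [c for c in [rec.at[m, "confirming_comparisons"]] if c]
            confirming.append(f"WBI_{WBI_COMPARISON}")
            rec.at[m, "confirming_comparisons"] = ";".join(confirming)
            q_wbi = wbi.at[m, "q"]
            rec.at[m, "min_q"] = np.fmin(rec.at[m, "min_q"], q_wbi)
            upgraded += 1

        if wli_sig and wbi_sig and np.isfinite(wli_ratio) and np.isfinite(wbi_ratio):
            same = (wli_ratio > 1) == (wbi_ratio > 1)
            rec.at[m, "cross_modality"] = MODALITY_SAME if same else MODALITY_OPPOSITE
        elif wli_sig and not wbi_sig:
            rec.at[m, "cross_modality"] = MODALITY_WLI_ONLY
        elif wbi_sig and not wli_sig:
            rec.at[m, "cross_modality"] = MODALITY_WBI_ONLY
        else:
            rec.at[m, "cross_modality"] = MODALITY_NA
    logger.info("cross-modality: %d single-level metabolites upgraded via WBI", upgraded)
    return rec.reset_index()


def records_to_dataset_layout(records: pd.DataFrame) -> pd.DataFrame:
    """Export cascade records in the X / YY boolean-flag dataset layout.

    One row per metabolite with an ``X_<comparison>`` column per confirming
    contrast, a ``YY`` flag for single-level unconfirmed metabolites, and the
    cross-modality label.
    """
    out = records[["metabolite", "tissue", "cascade_status", "cross_tissue", "cross_modality"]].copy()
    conf = records["confirming_comparisons"].fillna("").str.split(";")
    for c in COMPARISONS:
        out[f"X_{c}"] = [c in lst for lst in conf]
    out["X_WBI"] = [f"WBI_{WBI_COMPARISON}" in lst for lst in conf]
    out["YY"] = records["cascade_status"] == STATUS_UNCONFIRMED
    return out
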