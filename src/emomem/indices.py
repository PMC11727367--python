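"""Memory indices: signal-detection d' and the unbiased hit rate (Hu).

Item memory is indexed by d' = z(P Old) - z(P False Alarm).  For
Remember/Know data the two retrieval processes are separated under the
independence assumption: recollection d' uses Remember-restricted rates,

    d'_rec = z(P Remember) - z(P False Alarm Remember),

and familiarity d' conditions the Know rates on the absence of
recollection,

    d'_fam = z(K_hit / (1 - R_hit)) - z(K_fa / (1 - R_fa)).

Source (contextual) memory is indexed by the unbiased hit rate

    Hu = hits/(hits + incorrect) x hits/times_chosen,

the conjoint probability of correctly identifying a stimulus's source
category (stimulus accuracy) and of a response of that category being
correct when used (response precision).  Conditional Hu restricts the
counts to trials recognized under one memory judgment (Remember or Know).

Extreme rates (0 or 1) are nudged inside the unit interval by the 1/(2N)
rule before the normal quantile is taken, so every d' is finite.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import norm

from emomem.trial_io import INDEX_COLUMNS, harmonize_judgments

MEMORY_TYPES = ("overall", "remember", "know")
_CATEGORY_ORDER = ("neutral", "pleasant", "unpleasant")


class UndefinedRateError(ValueError):
    """A rate was requested with a zero denominator."""


class UndefinedIndexError(ValueError):
    """An index is undefined for these counts (reported as a missing cell)."""


def adjusted_proportion(successes: int, trials: int) -> float:
    """Proportion with the 1/(2N) correction for extreme counts.

    Returns ``successes/trials`` except that 0 maps to ``1/(2*trials)`` and
    ``trials`` maps to ``1 - 1/(2*trials)``, keeping the value strictly
    inside (0, 1) so the normal quantile stays finite.
    """
    if trials == 0:
        raise UndefinedRateError("rate undefined: zero trials")
    if trials < 0 or successes < 0 or successes > trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    if successes == 0:
        return 1.0 / (2.0 * trials)
    if successes == trials:
        return 1.0 - 1.0 / (2.0 * trials)
    return successes / trials


def z(p: float) -> float:
    """Standard-normal quantile; domain (0, 1) exclusive."""
    if not 0.0 < p < 1.0:
        raise UndefinedIndexError(f"z undefined for p={p} outside (0, 1)")
    return float(norm.ppf(p))


def item_dprime(hit_rate: float, fa_rate: float) -> float:
    """d' = z(hit rate) - z(false-alarm rate); rates already in (0, 1)."""
    return z(hit_rate) - z(fa_rate)


def recollection_dprime(remember_hit_rate: float, remember_fa_rate: float) -> float:
    """Recollection d' from Remember-restricted hit and false-alarm rates."""
    return z(remember_hit_rate) - z(remember_fa_rate)


def familiarity_dprime(
    remember_hit_rate: float,
    know_hit_rate: float,
    remember_fa_rate: float,
    know_fa_rate: float,
) -> float:
    """Familiarity d' under the independence assumption.

    Know rates are rescaled by the opportunity for a familiarity response,
    K/(1 - R), on both the hit and false-alarm side.  If either conditional
    ratio falls outside (0, 1) the index is undefined and
    :class:`UndefinedIndexError` is raised (the table builder reports such
    cells as missing).
    """
    hit_ratio = know_hit_rate / (1.0 - remember_hit_rate)
    fa_ratio = know_fa_rate / (1.0 - remember_fa_rate)
    for name, ratio in (("hit", hit_ratio), ("false-alarm", fa_ratio)):
        if not 0.0 < ratio < 1.0:
            raise UndefinedIndexError(
                f"familiarity d' undefined: conditional {name} ratio {ratio:.4g} "
                "outside (0, 1)"
            )
    return z(hit_ratio) - z(fa_ratio)


def unbiased_hit_rate(hits: int, incorrect: int, times_chosen: int) -> float:
    """Hu = stimulus accuracy x response precision.

    Returns ``hits/(hits+incorrect) * hits/times_chosen``; 0 when hits are
    zero but both denominators positive; NaN (missing) when either
    denominator is zero.
    """
    if min(hits, incorrect, times_chosen) < 0:
        raise ValueError("counts must be nonnegative")
    if hits + incorrect == 0 or times_chosen == 0:
        return math.nan
    return (hits / (hits + incorrect)) * (hits / times_chosen)


def source_counts(trials: pd.DataFrame, by_memory_type: bool = False) -> pd.DataFrame:
    """Source-attribution counts per participant x category (x judgment).

    Counts are taken over *old* items only; false-alarmed new items never
    enter any count.  ``times_chosen`` is the number of recognized old items
    in the stratum whose attribution named the category, right or wrong.

    Returns a tidy frame with columns ``participant``, ``memory_type``
    (``overall`` or, with ``by_memory_type=True``, ``remember``/``know``),
    ``context_category``, ``hits``, ``incorrect``, ``times_chosen``.
    """
    df = trials if "old_judgment" in trials.columns else harmonize_judgments(trials)
    old = df[(df["item_status"] == "old") & df["old_judgment"]].copy()
    if by_memory_type:
        old = old[old["recognition_response"].isin(("remember", "know"))]
        old["memory_type"] = old["recognition_response"]
        strata = ("remember", "know")
    else:
        old["memory_type"] = "overall"
        strata = ("overall",)

    answered = old[old["source_response"].notna()]
    keys = ["participant", "memory_type", "context_category"]

    # category cells are defined by what each participant encoded, so empty
    # strata still appear with zero counts
    encoded = (
        df[df["item_status"] == "old"]
        .groupby(["participant", "context_category"], sort=True)
        .size()
        .reset_index()[["participant", "context_category"]]
    )
    grid = encoded.merge(pd.DataFrame({"memory_type": strata}), how="cross")

    if len(answered):
        correct = answered["source_response"] == answered["context_category"]
        acc = (
            answered.assign(_hit=correct)
            .groupby(keys, sort=False)["_hit"]
            .agg(hits="sum", total="count")
            .reset_index()
        )
        acc["incorrect"] = acc["total"] - acc["hits"]
        chosen = (
            answered.groupby(["participant", "memory_type", "source_response"], sort=False)
            .size()
            .rename("times_chosen")
            .reset_index()
            .rename(columns={"source_response": "context_category"})
        )
    else:
        acc = pd.DataFrame(columns=keys + ["hits", "total", "incorrect"])
        chosen = pd.DataFrame(columns=keys + ["times_chosen"])

    out = grid.merge(acc[keys + ["hits", "incorrect"]], on=keys, how="left")
    out = out.merge(chosen, on=keys, how="left")
    for col in ("hits", "incorrect", "times_chosen"):
        out[col] = pd.to_numeric(out[col], errors="coerce").fillna(0).astype(int)
    return out.sort_values(keys, kind="stable").reset_index(drop=True)


def _adjusted_vec(successes: pd.Series, trials: pd.Series) -> np.ndarray:
    s = successes.to_numpy(dtype=float)
    n = trials.to_numpy(dtype=float)
    if (n == 0).any():
        raise UndefinedRateError("rate undefined: zero trials")
    p = s / n
    p = np.where(s == 0, 1.0 / (2.0 * n), p)
    p = np.where(s == n, 1.0 - 1.0 / (2.0 * n), p)
    return p


def _safe_z(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, np.nan)
    ok = (p > 0.0) & (p < 1.0)
    out[ok] = norm.ppf(p[ok])
    return out


def _participant_meta(df: pd.DataFrame) -> pd.DataFrame:
    cols = [
        "participant",
        "study",
        "group",
        "environment",
        "encoding_instruction",
        "retrieval_task",
        "n_new_items",
    ]
    return df[cols].drop_duplicates("participant").set_index("participant")


def build_index_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Score a validated trial table into the participant-level index table.

    Two analysis sets are emitted:

    * ``memory_type == "overall"`` rows for every participant x encoded
      category, with d' computed from harmonized old/new judgments and the
      overall Hu;
    * for Remember/Know participants, ``remember`` and ``know`` rows with
      recollection d', familiarity d' (independence assumption), and the
      judgment-conditional Hu.

    All rates pass through :func:`adjusted_proportion` before the normal
    quantile.  Cells whose index is undefined (zero Hu denominator, or a
    conditional familiarity ratio outside the unit interval) are missing
    (NaN), never zero.
    """
    df = trials if "old_judgment" in trials.columns else harmonize_judgments(trials)
    if not len(df):
        raise ValueError("empty trial table")
    meta = _participant_meta(df)

    new = df[df["item_status"] == "new"]
    new_counts = new.groupby("participant").agg(
        n_new=("old_judgment", "size"),
        fa=("old_judgment", "sum"),
        r_fa=("recognition_response", lambda s: int((s == "remember").sum())),
        k_fa=("recognition_response", lambda s: int((s == "know").sum())),
    )
    missing_new = meta.index.difference(new_counts.index)
    if len(missing_new):
        raise UndefinedRateError(
            f"d' undefined: participant(s) {sorted(missing_new)} have no new trials"
        )

    old = df[df["item_status"] == "old"]
    cell = old.groupby(["participant", "context_category"]).agg(
        n_old=("old_judgment", "size"),
        hits=("old_judgment", "sum"),
        r_hits=("recognition_response", lambda s: int((s == "remember").sum())),
        k_hits=("recognition_response", lambda s: int((s == "know").sum())),
    ).reset_index()
    cell = cell.join(new_counts, on="participant")

    hu_overall = source_counts(df, by_memory_type=False)
    hu_mem = source_counts(df, by_memory_type=True)

    def hu_col(counts: pd.DataFrame) -> np.ndarray:
        h = counts["hits"].to_numpy(dtype=float)
        inc = counts["incorrect"].to_numpy(dtype=float)
        tc = counts["times_chosen"].to_numpy(dtype=float)
        out = np.full(len(counts), np.nan)
        ok = (h + inc > 0) & (tc > 0)
        out[ok] = (h[ok] / (h[ok] + inc[ok])) * (h[ok] / tc[ok])
        return out

    # -- overall rows -------------------------------------------------------
    overall = cell.copy()
    overall["d_prime"] = _safe_z(_adjusted_vec(overall["hits"], overall["n_old"])) - _safe_z(
        _adjusted_vec(overall["fa"], overall["n_new"])
    )
    hu_o = hu_overall[hu_overall["memory_type"] == "overall"].copy()
    hu_o["hu"] = hu_col(hu_o)
    overall = overall.merge(
        hu_o[["participant", "context_category", "hu"]],
        on=["participant", "context_category"],
        how="left",
    )
    overall["memory_type"] = "overall"

    # -- memory-type rows (Remember/Know participants only) ------------------
    rk = cell[cell["participant"].map(meta["retrieval_task"]) == "remember_know"].copy()
    mem_rows = []
    if len(rk):
        r_hit = _adjusted_vec(rk["r_hits"], rk["n_old"])
        k_hit = _adjusted_vec(rk["k_hits"], rk["n_old"])
        r_fa = _adjusted_vec(rk["r_fa"], rk["n_new"])
        k_fa = _adjusted_vec(rk["k_fa"], rk["n_new"])

        rem = rk.copy()
        rem["memory_type"] = "remember"
        rem["d_prime"] = _safe_z(r_hit) - _safe_z(r_fa)

        kno = rk.copy()
        kno["memory_type"] = "know"
        with np.errstate(divide="ignore", invalid="ignore"):
            hit_ratio = k_hit / (1.0 - r_hit)
            fa_ratio = k_fa / (1.0 - r_fa)
        kno["d_prime"] = _safe_z(hit_ratio) - _safe_z(fa_ratio)

        hu_m = hu_mem.copy()
        hu_m["hu"] = hu_col(hu_m)
        hu_key = ["participant", "context_category", "memory_type"]
        rem = rem.merge(
            hu_m[hu_m["memory_type"] == "remember"][hu_key + ["hu"]],
            on=hu_key, how="left",
        )
        kno = kno.merge(
            hu_m[hu_m["memory_type"] == "know"][hu_key + ["hu"]],
            on=hu_key, how="left",
        )
        mem_rows = [rem, kno]

    table = pd.concat([overall, *mem_rows], ignore_index=True)
    table = table.rename(columns={"context_category": "affective_category"})
    for col in meta.columns:
        table[col] = table["participant"].map(meta[col])

    table["memory_type"] = pd.Categorical(
        table["memory_type"], categories=list(MEMORY_TYPES), ordered=True
    )
    table["affective_category"] = pd.Categorical(
        table["affective_category"], categories=list(_CATEGORY_ORDER), ordered=True
    )
    table = table.sort_values(
        ["participant", "memory_type", "affective_category"], kind="stable"
    ).reset_index(drop=True)
    table["memory_type"] = table["memory_type"].astype(str)
    table["affective_category"] = table["affective_category"].astype(str)
    return table[INDEX_COLUMNS]
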