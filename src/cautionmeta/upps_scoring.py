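"""Scoring of the 59-item UPPS-P impulsive-behaviour scale.

Responses are 4-point Likert ratings (1 = Agree strongly .. 4 = Disagree
strongly).  Items belong to one of five subscales — negative urgency,
(lack of) premeditation, (lack of) perseverance, sensation seeking,
positive urgency — and reverse-coded items are mapped r -> 5 - r before
summing, so that a high subscale score always indicates higher
impulsivity.  When a questionnaire was administered in both sessions of a
two-session study, subscale scores are averaged across sessions.

The item -> subscale key ships as data (a DataFrame / CSV), not code: the
default key reproduces the published per-subscale item counts
(12/11/10/12/14) with a generic reversal pattern, and users can supply the
instrument's exact key as a CSV with columns item_id, subscale, reversed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SUBSCALES = (
    "negative_urgency",
    "premeditation",
    "perseverance",
    "sensation_seeking",
    "positive_urgency",
)

#: published per-subscale item counts (59 items total)
SUBSCALE_N_ITEMS = {
    "negative_urgency": 12,
    "premeditation": 11,
    "perseverance": 10,
    "sensation_seeking": 12,
    "positive_urgency": 14,
}

N_ITEMS = 59


def default_scoring_key() -> pd.DataFrame:
    """Generic 59-item scoring key.

    Items are numbered 1..59 grouped by subscale.  Urgency and
    sensation-seeking items (statements describing impulsive behaviour,
    where agreement = 1 signals impulsivity) are reverse-coded; the
    premeditation and perseverance items (statements describing planful
    behaviour) are not.  Under the 1 = Agree .. 4 = Disagree response scale
    this orients every subscale so that high score = high impulsivity.
    """
    rows = []
    item = 1
    for sub in SUBSCALES:
        reversed_flag = sub in ("negative_urgency", "sensation_seeking", "positive_urgency")
        for _ in range(SUBSCALE_N_ITEMS[sub]):
            rows.append({"item_id": item, "subscale": sub, "reversed": reversed_flag})
            item += 1
    return pd.DataFrame(rows)


def validate_key(key: pd.DataFrame) -> None:
    for col in ("item_id", "subscale", "reversed"):
        if col not in key.columns:
            raise ValueError(f"scoring key missing column {col!r}")
    if key["item_id"].duplicated().any():
        raise ValueError("scoring key assigns an item to more than one row")
    bad = set(key["subscale"]) - set(SUBSCALES)
    if bad:
        raise ValueError(f"unknown subscales in key: {sorted(bad)}")


def read_scoring_key(path) -> pd.DataFrame:
    key = pd.read_csv(path)
    key["reversed"] = key["reversed"].astype(bool)
    validate_key(key)
    return key


def write_scoring_key(key: pd.DataFrame, path) -> None:
    validate_key(key)
    key.to_csv(path, index=False)


def score_items(responses: pd.DataFrame, key: pd.DataFrame | None = None,
                missing: str = "strict") -> pd.DataFrame:
    """Score item responses into per-session subscale totals.

    Parameters
    ----------
    responses
        Long table with columns subject_id, session, item_id, response
        (integers 1-4).
    key
        Scoring key; defaults to :func:`default_scoring_key`.
    missing
        ``"strict"`` (default): a subject/session subscale is NaN if any of
        its items is missing.  ``"impute_mean"``: missing items are
        replaced by the mean of the subject's observed items on that
        subscale.

    Returns a long table (subject_id, session, subscale, score).
    """
    key = default_scoring_key() if key is None else key
    validate_key(key)
    for col in ("subject_id", "session", "item_id", "response"):
        if col not in responses.columns:
            raise ValueError(f"responses missing column {col!r}")
    resp = responses.copy()
    vals = resp["response"].to_numpy()
    present = ~pd.isna(vals)
    arr = vals[present]
    if not np.all((arr == np.round(arr.astype(float))) & (arr >= 1) & (arr <= 4)):
        raise ValueError("responses must be integers in 1..4")
    merged = resp.merge(key, on="item_id", how="left")
    if merged["subscale"].isna().any():
        bad = merged.loc[merged["subscale"].isna(), "item_id"].iloc[0]
        raise ValueError(f"item {bad} not in scoring key")
    scored = np.where(merged["reversed"].to_numpy(bool),
                      5.0 - merged["response"].to_numpy(float),
                      merged["response"].to_numpy(float))
    merged["scored"] = scored

    n_items = key.groupby("subscale")["item_id"].nunique()
    agg = (merged.groupby(["subject_id", "session", "subscale"], sort=True)["scored"]
           .agg(total="sum", n_obs="count").reset_index())
    expected = agg["subscale"].map(n_items).to_numpy(float)
    total = agg["total"].to_numpy(float)
    n_obs = agg["n_obs"].to_numpy(float)
    complete = n_obs >= expected
    if missing == "strict":
        score = np.where(complete, total, np.nan)
    elif missing == "impute_mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            imputed = total + (total / n_obs) * (expected - n_obs)
        score = np.where(complete, total, np.where(n_obs > 0, imputed, np.nan))
    else:
        raise ValueError("missing must be 'strict' or 'impute_mean'")
    agg["score"] = score
    return agg[["subject_id", "session", "subscale", "score"]]


def average_sessions(scores_by_session: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of subscale scores across sessions per subject.

    A single session passes through unchanged.  Returns (subject_id,
    subscale, score, sessions_used).
    """
    for col in ("subject_id", "session", "subscale", "score"):
        if col not in scores_by_session.columns:
            raise ValueError(f"scores missing column {col!r}")
    if len(scores_by_session) == 0:
        raise ValueError("no sessions provided")
    agg = (scores_by_session.groupby(["subject_id", "subscale"], sort=True)
           .agg(score=("score", "mean"), sessions_used=("session", "nunique"))
           .reset_index())
    return agg


def score_questionnaire(responses: pd.DataFrame, key: pd.DataFrame | None = None,
                        missing: str = "strict") -> pd.DataFrame:
    """Convenience: score items then average across sessions."""
    return average_sessions(score_items(responses, key, missing))
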