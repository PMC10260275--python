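"""Recognition-memory scoring over three retrievals.

The task: 150 encoded pictures (75 neutral then 75 negative); each retrieval
(immediate, 12 h, 24 h) presents 50 targets and 50 foils, 25 neutral and 25
emotional within each.  Responses are recollected / familiar / new.  Hits
count targets called old (recollected or familiar; in recollection mode only
"recollected"), false alarms foils called old.  Discriminability is

    d' = z(hit rate) − z(false-alarm rate)

with extreme rates (0 or 1) replaced by 1/(2n) and 1 − 1/(2n) before the
normal quantile (log-linear +0.5 correction available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "RETRIEVALS",
    "EMOTIONS",
    "OLD_RESPONSES",
    "validate_response_table",
    "score_rates",
    "dprime",
    "score_table",
    "difference_scores",
    "scores_to_array",
    "RESPONSE_BUTTON_MAP",
]

RETRIEVALS = ("immediate", "12h", "24h")
EMOTIONS = ("neutral", "emotional")
OLD_RESPONSES = frozenset({"recollected", "familiar"})

#: button codes used in the task: 1 = recollection, 2 = familiar, 0 = new
RESPONSE_BUTTON_MAP = {"1": "recollected", "2": "familiar", "0": "new",
                       1: "recollected", 2: "familiar", 0: "new"}

REQUIRED_COLUMNS = ("subject", "retrieval", "item_id", "emotion", "is_target",
                    "response")


class ScoringError(ValueError):
    pass


def normalize_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Map numeric button codes to response labels; leave labels untouched."""
    out = table.copy()
    out["response"] = out["response"].map(
        lambda r: RESPONSE_BUTTON_MAP.get(r, r))
    return out


def validate_response_table(table: pd.DataFrame, lenient: bool = False) -> None:
    """Check the task-design invariants (50 targets + 50 foils, 25/25 per
    emotion) per subject × retrieval.  ``lenient`` skips the count checks."""
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ScoringError(f"response table missing columns: {sorted(missing)}")
    bad = set(table["response"]) - {"recollected", "familiar", "new"}
    if bad:
        raise ScoringError(f"unknown responses: {sorted(bad)}")
    if lenient:
        return
    counts = (table.groupby(["subject", "retrieval", "emotion", "is_target"])
              .size())
    if not (counts == 25).all():
        off = counts[counts != 25]
        raise ScoringError(f"task design violated (expect 25 per cell): {off.head()}")


def score_rates(table: pd.DataFrame, mode: str = "total",
                lenient: bool = False) -> pd.DataFrame:
    """Hit and false-alarm rates per subject × retrieval × emotion.

    ``mode='total'`` counts recollected+familiar as old; ``'recollection'``
    counts only recollected.
    """
    if mode not in ("total", "recollection"):
        raise ValueError(f"unknown mode {mode!r}")
    table = normalize_responses(table)
    validate_response_table(table, lenient=lenient)
    old = ({"recollected", "familiar"} if mode == "total" else {"recollected"})
    t = table.assign(said_old=table["response"].isin(old))
    rows = []
    for (subj, ret, emo), g in t.groupby(["subject", "retrieval", "emotion"]):
        targets = g[g["is_target"]]
        foils = g[~g["is_target"]]
        if len(targets) == 0 or len(foils) == 0:
            raise ScoringError(
                f"no targets or foils in cell subject={subj}, retrieval={ret}, "
                f"emotion={emo}")
        rows.append({
            "subject": subj, "retrieval": ret, "emotion": emo,
            "n_targets": len(targets), "n_foils": len(foils),
            "hit_rate": targets["said_old"].mean(),
            "fa_rate": foils["said_old"].mean(),
        })
    return pd.DataFrame(rows)


def _correct_rate(rate: float, n: int, correction: str) -> float:
    if correction == "loglinear":
        # applied unconditionally in the log-linear scheme
        return (rate * n + 0.5) / (n + 1)
    if rate <= 0.0:
        return 1.0 / (2 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def dprime(hit: float, fa: float, n_targets: int = 25, n_foils: int = 25,
           correction: str = "half_count") -> float:
    """d' = z(hit) − z(fa), with extreme-rate correction."""
    if not (0 <= hit <= 1 and 0 <= fa <= 1):
        raise ValueError("rates must lie in [0, 1]")
    h = _correct_rate(hit, n_targets, correction)
    f = _correct_rate(fa, n_foils, correction)
    return float(norm.ppf(h) - norm.ppf(f))


def score_table(table: pd.DataFrame, mode: str = "total",
                correction: str = "half_count",
                lenient: bool = False) -> pd.DataFrame:
    """Full scoring: rates plus d' per subject × retrieval × emotion."""
    rates = score_rates(table, mode=mode, lenient=lenient)
    rates["dprime"] = [
        dprime(r.hit_rate, r.fa_rate, int(r.n_targets), int(r.n_foils), correction)
        for r in rates.itertuples()
    ]
    return rates


@dataclass
class DifferenceScores:
    """Per-subject time and emotion difference scores of d'."""

    frame: pd.DataFrame  # columns: subject, name, value


def difference_scores(scores: pd.DataFrame, value: str = "dprime") -> pd.DataFrame:
    """Difference scores per subject from a long-format scores frame.

    Time: immediate − 12h and 12h − 24h (per emotion and pooled over
    emotions); emotion: neutral − emotional (per retrieval and pooled).
    Missing cells propagate as NaN.
    """
    wide = scores.pivot_table(index="subject", columns=["retrieval", "emotion"],
                              values=value, aggfunc="first")
    out = pd.DataFrame(index=wide.index)

    def cell(ret, emo):
        return wide.get((ret, emo), pd.Series(np.nan, index=wide.index))

    pooled = {ret: (cell(ret, "neutral") + cell(ret, "emotional")) / 2
              for ret in RETRIEVALS}
    for emo in EMOTIONS:
        out[f"time_imm_12h_{emo}"] = cell("immediate", emo) - cell("12h", emo)
        out[f"time_12h_24h_{emo}"] = cell("12h", emo) - cell("24h", emo)
    out["time_imm_12h"] = pooled["immediate"] - pooled["12h"]
    out["time_12h_24h"] = pooled["12h"] - pooled["24h"]
    for ret in RETRIEVALS:
        out[f"emotion_{ret}"] = cell(ret, "neutral") - cell(ret, "emotional")
    out["emotion_pooled"] = sum(out[f"emotion_{r}"] for r in RETRIEVALS) / 3
    return out.reset_index()


def scores_to_array(scores: pd.DataFrame, value: str = "dprime") -> tuple[np.ndarray, list]:
    """(n_subjects, 3 retrievals, 2 emotions) array + subject order."""
    wide = scores.pivot_table(index="subject", columns=["retrieval", "emotion"],
                              values=value, aggfunc="first")
    subjects = list(wide.index)
    arr = np.empty((len(subjects), len(RETRIEVALS), len(EMOTIONS)))
    for j, ret in enumerate(RETRIEVALS):
        for k, emo in enumerate(EMOTIONS):
            arr[:, j, k] = wide[(ret, emo)].to_numpy()
    return arr, subjects
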