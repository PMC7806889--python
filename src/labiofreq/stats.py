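"""Labiodental usage statistics.

For every doculect we tabulate, over all word forms, the total number of
consonant tokens ``C``, the number of labiodental tokens ``F``, and the number
of word-initial labiodental tokens ``F_wi`` (a word's first segment, when it
is a labiodental consonant).  The two headline statistics are

    LR   = F / C        (labiodental ratio)
    WILR = F_wi / C     (word-initial labiodental ratio)

Note that WILR divides by *all* consonant tokens, not by word-initial ones,
so WILR <= LR always holds.

Because both are ratios bounded at 0 and 1 — and more than half of the word
lists in a worldwide sample contain no labiodental at all — the default
transform for linear modelling is the logit of the Smithson-Verkuilen
compressed ratio y = (x (N-1) + 1/2) / N, which maps the boundary values
into the open interval using the dataset size N.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .segments import SegmentClassTable
from .wordlists import Doculect

__all__ = [
    "LabiodentalProfile",
    "ZeroConsonantError",
    "profile_doculect",
    "profile_doculects",
    "profiles_frame",
    "transform_ratio",
    "summarize_by_group",
    "TestResult",
    "pearson_chi_square",
]

logger = logging.getLogger(__name__)


class ZeroConsonantError(ValueError):
    """The doculect has no consonant token, so LR is undefined."""


@dataclass(frozen=True)
class LabiodentalProfile:
    """Per-doculect labiodental token counts and ratios."""

    doculect_id: str
    n_consonants: int
    n_labiodental: int
    n_wi_labiodental: int
    iso_code: str | None = None
    glottocode: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_wi_labiodental <= self.n_labiodental <= self.n_consonants:
            raise ValueError(
                "counts must satisfy 0 <= word-initial <= labiodental <= consonants, "
                f"got {self.n_wi_labiodental}/{self.n_labiodental}/{self.n_consonants}"
            )

    @property
    def lr(self) -> float:
        return self.n_labiodental / self.n_consonants

    @property
    def wilr(self) -> float:
        return self.n_wi_labiodental / self.n_consonants

    @property
    def has_labiodental(self) -> bool:
        return self.n_labiodental >= 1


def profile_doculect(
    d: Doculect, classes: SegmentClassTable | None = None
) -> LabiodentalProfile:
    """Tabulate consonant and labiodental tokens over all forms of a doculect.

    Every transcription variant counts; a word-initial labiodental is a form
    whose first token is in the labiodental class.  Raises
    :class:`ZeroConsonantError` when no form contains a consonant token.
    """
    if classes is None:
        classes = SegmentClassTable.default("asjp")
    consonants = classes.consonants
    labiodentals = classes.labiodentals
    n_c = n_f = n_wi = 0
    for form in d.forms:
        for pos, tok in enumerate(form.tokens):
            if tok in consonants:
                n_c += 1
                if tok in labiodentals:
                    n_f += 1
                    if pos == 0:
                        n_wi += 1
    if n_c == 0:
        raise ZeroConsonantError(
            f"doculect {d.doculect_id!r} has no consonant token in {len(d.forms)} forms"
        )
    return LabiodentalProfile(
        doculect_id=d.doculect_id,
        n_consonants=n_c,
        n_labiodental=n_f,
        n_wi_labiodental=n_wi,
        iso_code=d.iso_code,
        glottocode=d.glottocode,
    )


def profile_doculects(
    doculects: list[Doculect], classes: SegmentClassTable | None = None
) -> tuple[list[LabiodentalProfile], list[str]]:
    """Profile a dataset; consonant-free doculects are excluded and logged.

    Returns the profiles and the ids of excluded doculects.
    """
    profiles, excluded = [], []
    for d in doculects:
        try:
            profiles.append(profile_doculect(d, classes))
        except ZeroConsonantError as exc:
            logger.warning("excluding doculect: %s", exc)
            excluded.append(d.doculect_id)
    return profiles, excluded


def profiles_frame(profiles: list[LabiodentalProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame with a stable column order."""
    return pd.DataFrame(
        {
            "doculect_id": [p.doculect_id for p in profiles],
            "iso_code": [p.iso_code for p in profiles],
            "glottocode": [p.glottocode for p in profiles],
            "n_consonants": [p.n_consonants for p in profiles],
            "n_labiodental": [p.n_labiodental for p in profiles],
            "n_wi_labiodental": [p.n_wi_labiodental for p in profiles],
            "lr": [p.lr for p in profiles],
            "wilr": [p.wilr for p in profiles],
        }
    )


def transform_ratio(x, n: int | None = None, method: str = "logit_smoothed"):
    """Map a ratio in [0, 1] onto the real line for linear modelling.

    ``logit_smoothed`` applies the Smithson-Verkuilen compression
    y = (x (N-1) + 1/2) / N with N = ``n`` (the number of doculects in the
    dataset) before the logit, so boundary values stay finite.  ``raw_logit``
    is log(x / (1-x)) and raises on x in {0, 1}.

    Accepts scalars or array-likes; returns the same shape.
    """
    arr = np.asarray(x, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("ratios must lie in [0, 1]")
    if method == "logit_smoothed":
        if n is None or n < 1:
            raise ValueError("logit_smoothed needs the dataset size n >= 1")
        y = (arr * (n - 1) + 0.5) / n
        out = np.log(y / (1.0 - y))
    elif method == "raw_logit":
        if np.any((arr == 0) | (arr == 1)):
            raise ValueError(
                "raw_logit is undefined at 0 and 1; use method='logit_smoothed'"
            )
        out = np.log(arr / (1.0 - arr))
    else:
        raise ValueError(f"unknown transform method {method!r}")
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def summarize_by_group(
    profiles: list[LabiodentalProfile] | pd.DataFrame,
    labels: dict[str, str] | pd.Series | None = None,
    all_label: str = "all",
) -> pd.DataFrame:
    """Unweighted per-group mean and SD of LR and WILR, plus an overall row.

    ``labels`` maps doculect_id to a group name (e.g. HG / nonHG); when a
    DataFrame is passed it may instead carry a ``group`` column.  Groups with
    no members are simply absent; every profile must have a label.
    """
    frame = profiles if isinstance(profiles, pd.DataFrame) else profiles_frame(profiles)
    frame = frame.copy()
    if labels is not None:
        mapped = frame["doculect_id"].map(dict(labels) if not isinstance(labels, pd.Series) else labels)
        frame["group"] = mapped
    if "group" not in frame.columns:
        raise ValueError("no group labels supplied")
    if frame["group"].isna().any():
        missing = frame.loc[frame["group"].isna(), "doculect_id"].tolist()
        raise ValueError(f"profiles without a group label: {missing[:5]}")

    def _rows(sub: pd.DataFrame, label: str) -> dict:
        return {
            "group": label,
            "n": len(sub),
            "lr_mean": sub["lr"].mean(),
            "lr_sd": sub["lr"].std(ddof=1) if len(sub) > 1 else 0.0,
            "wilr_mean": sub["wilr"].mean(),
            "wilr_sd": sub["wilr"].std(ddof=1) if len(sub) > 1 else 0.0,
        }

    rows = [_rows(frame, all_label)]
    for label, sub in frame.groupby("group", sort=True):
        rows.append(_rows(sub, str(label)))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TestResult:
    """A chi-square style test outcome (statistic, df, upper-tail p)."""

    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0 <= self.p_value <= 1:
            raise ValueError("invalid test result")


def pearson_chi_square(table) -> TestResult:
    """Uncorrected Pearson chi-square test of independence on a 2x2 table.

    For counts [[a, b], [c, d]] the statistic is n (ad - bc)^2 / (r1 r2 c1 c2)
    with row sums r and column sums c; no continuity correction is applied.
    Raises on a zero marginal (test undefined).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal: chi-square test undefined")
    n = t.sum()
    (a, b), (c, d) = t
    statistic = n * (a * d - b * c) ** 2 / (rows[0] * rows[1] * cols[0] * cols[1])
    p = float(sps.chi2.sf(statistic, df=1))
    return TestResult(statistic=float(statistic), df=1, p_value=p)
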