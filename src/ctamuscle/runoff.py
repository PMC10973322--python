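"""Modified SVS runoff scoring, severity dichotomization, reader agreement.

The runoff score summarizes patency of the lower-leg arterial tree on a
0-19 scale (higher = more severe).  The default rubric grades six crural
artery segments 0-3 each plus a pedal-arch segment 0-1, giving the 0-19
range; segments, grade scales, weights and offset are fully configurable
because published variants of the score differ in their segment tables.

Severity is dichotomized on the DSA score at 7 (mild <= 7 < severe), and
inter-reader agreement is quantified with a two-way random-effects,
absolute-agreement, single-rater ICC (ICC(2,1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RunoffRubric",
    "default_rubric",
    "runoff_score",
    "dichotomize",
    "icc_agreement",
    "ICCResult",
]

SEVERITY_CUTOFF = 7.0


@dataclass(frozen=True)
class RunoffRubric:
    """Segment names, allowed integer grades, weights and additive offset."""

    segments: tuple[str, ...]
    grade_scale: dict[str, tuple[int, ...]]
    weights: dict[str, float] | None = None
    offset: float = 0.0

    def __post_init__(self) -> None:
        for seg in self.segments:
            if seg not in self.grade_scale:
                raise ValueError(f"no grade scale for segment {seg!r}")
        if self.weights is not None:
            for seg in self.segments:
                if seg not in self.weights:
                    raise ValueError(f"no weight for segment {seg!r}")

    def weight(self, seg: str) -> float:
        return 1.0 if self.weights is None else self.weights[seg]

    @property
    def max_score(self) -> float:
        return self.offset + sum(max(self.grade_scale[s]) * self.weight(s) for s in self.segments)

    @property
    def min_score(self) -> float:
        return self.offset + sum(min(self.grade_scale[s]) * self.weight(s) for s in self.segments)


def default_rubric() -> RunoffRubric:
    """Six crural segments graded 0-3 plus a pedal arch graded 0-1 (max 19)."""
    crural = (
        "anterior_tibial_proximal",
        "anterior_tibial_distal",
        "posterior_tibial_proximal",
        "posterior_tibial_distal",
        "peroneal_proximal",
        "peroneal_distal",
    )
    segments = crural + ("pedal_arch",)
    scale: dict[str, tuple[int, ...]] = {s: (0, 1, 2, 3) for s in crural}
    scale["pedal_arch"] = (0, 1)
    return RunoffRubric(segments=segments, grade_scale=scale)


def runoff_score(grades: dict[str, int], rubric: RunoffRubric | None = None) -> float:
    """Weighted sum of per-segment stenosis grades plus the rubric offset."""
    rubric = rubric or default_rubric()
    unknown = set(grades) - set(rubric.segments)
    if unknown:
        raise ValueError(f"unknown segments: {sorted(unknown)}")
    missing = set(rubric.segments) - set(grades)
    if missing:
        raise ValueError(f"ungraded segments: {sorted(missing)}")
    total = rubric.offset
    for seg in rubric.segments:
        g = grades[seg]
        if g not in rubric.grade_scale[seg]:
            raise ValueError(
                f"grade {g} out of scale {rubric.grade_scale[seg]} for segment {seg!r}"
            )
        total += rubric.weight(seg) * g
    return float(total)


def dichotomize(dsa_score: float) -> str:
    """'mild' iff the DSA runoff score is <= 7, else 'severe'."""
    if not 0.0 <= dsa_score <= 19.0:
        raise ValueError(f"runoff score must be in [0, 19], got {dsa_score}")
    return "mild" if dsa_score <= SEVERITY_CUTOFF else "severe"


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    warning: str | None = None


def icc_agreement(reader1, reader2) -> ICCResult:
    """ICC(2,1) between two readers' scores with an F-based 95% CI."""
    r1 = np.asarray(reader1, dtype=float)
    r2 = np.asarray(reader2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("reader score vectors must be 1D and equal length")
    n = r1.size
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if np.var(np.concatenate([r1, r2])) == 0 or np.var((r1 + r2) / 2.0) == 0:
        return ICCResult(0.0, 0.0, 0.0, 1.0, warning="zero between-subject variance")

    import pingouin as pg

    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["r1", "r2"], n),
            "score": np.concatenate([r1, r2]),
        }
    )
    res = pg.intraclass_corr(data=df, targets="subject", raters="rater", ratings="score")
    # absolute-agreement, single-rater, two-way random: labelled ICC2 or
    # ICC(A,1) depending on the pingouin version
    match = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    row = match.iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(float(row["ICC"]), float(lo), float(hi), float(row["pval"]))
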