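"""Five-segment sub-dataset analysis along the knee->ankle axis.

The segmented region is split into k (default 5) contiguous, disjoint
z-segments of near-equal slice count (remainder slices assigned
proximal-first).  The model's input features are re-extracted from each
segment alone, standardized with the *whole-leg* transform parameters
(re-standardizing per segment would leak test information), and pushed
through the fitted or published logistic equations at their fixed
cutoffs - cutoffs are deliberately not re-optimized per segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import DiscretizationParams
from .features.extract import extract_features
from .modeling import PUBLISHED_MODELS, ModelReport, _delong_variance
from .screening import ZScoreTransform
from .segmentation import MuscleMask, restrict_z
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["SubsetPartition", "split_z", "evaluate_subsets", "evaluate_at_cutoff"]


@dataclass(frozen=True)
class SubsetPartition:
    k: int
    boundaries: tuple[int, ...]  # k+1 slice indices; segment i = [b[i], b[i+1])

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) != self.k + 1 or any(b[i] >= b[i + 1] for i in range(self.k)):
            raise ValueError(f"invalid partition boundaries {b}")


def make_partition(z_start: int, z_end: int, k: int) -> SubsetPartition:
    """Near-equal split of the inclusive range; remainder goes proximal."""
    length = z_end - z_start + 1
    if length < k:
        raise ValueError(f"z range of {length} slices cannot be split into {k} segments")
    base, rem = divmod(length, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    bounds = [z_start]
    for s in sizes:
        bounds.append(bounds[-1] + s)
    return SubsetPartition(k=k, boundaries=tuple(bounds))


def split_z(mask: MuscleMask, k: int = 5) -> list[MuscleMask]:
    """Partition a mask into k contiguous z-segments, knee -> ankle."""
    z0, z1 = mask.z_range if mask.z_range is not None else (0, mask.mask.shape[2] - 1)
    part = make_partition(z0, z1, k)
    out = []
    for i in range(k):
        out.append(restrict_z(mask, part.boundaries[i], part.boundaries[i + 1] - 1))
    return out


def evaluate_at_cutoff(scores, labels, cutoff: float) -> dict:
    """AUC (DeLong CI) plus sensitivity/specificity/accuracy at a fixed cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc, var = _delong_variance(scores, labels)
    se = np.sqrt(var)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)) if se > 0 else (auc, auc)
    p = float(2.0 * stats.norm.sf(abs(auc - 0.5) / se)) if se > 0 else float(auc != 0.5)
    pred = scores >= cutoff
    pos = labels == 1
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    return {
        "auc": float(auc),
        "auc_ci_low": ci[0],
        "auc_ci_high": ci[1],
        "auc_p": p,
        "sensitivity": tp / n_pos,
        "specificity": tn / n_neg,
        "accuracy": (tp + tn) / (n_pos + n_neg),
        "cutoff": float(cutoff),
    }


def _model_equation(model, name: str):
    """Normalize a fitted report or published variant to (coefs, const, cutoff)."""
    if isinstance(model, ModelReport):
        cutoff = model.roc.cutoff if model.roc is not None else 0.5
        return model.coefficients, model.constant, cutoff
    if isinstance(model, str) and model in PUBLISHED_MODELS:
        spec = PUBLISHED_MODELS[model]
        return spec["coefficients"], spec["constant"], spec["cutoff"]
    raise ValueError(f"model {name!r} must be a ModelReport or a published variant name")


def evaluate_subsets(
    volumes,
    masks,
    groups,
    models: dict,
    ztransform: ZScoreTransform,
    cta_z=None,
    disc: DiscretizationParams | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """Re-extract model inputs per z-segment and score every model on each.

    ``models`` maps a display name to a fitted :class:`ModelReport` or a
    published-variant string.  ``cta_z`` (standardized CTA score per
    subject) is required by models whose equation includes ``cta_score``.
    Subjects with an empty segment mask are excluded from that segment with
    a log entry.
    """
    disc = disc or DiscretizationParams()
    groups = np.asarray(groups)
    y = (groups == "severe").astype(int)
    n = len(volumes)
    if not (len(masks) == n == len(groups)):
        raise ValueError("volumes, masks and groups must be aligned")

    # union of muscle-feature inputs needed by any model
    needed: set[str] = set()
    eqs = {}
    for name, model in models.items():
        coefs, const, cutoff = _model_equation(model, name)
        eqs[name] = (coefs, const, cutoff)
        needed |= {v for v in coefs if v != "cta_score"}
    needed_list = sorted(needed)

    rows = []
    for s_idx in range(k):
        feats = {}
        excluded = []
        for i in range(n):
            seg = split_z(masks[i], k)[s_idx]
            if seg.n_voxels == 0:
                excluded.append(i)
                log.warning("subset %d: subject %d has an empty segment mask; excluded", s_idx + 1, i)
                continue
            feats[i] = extract_features(volumes[i], seg, needed_list, disc)
        idx = [i for i in range(n) if i not in excluded]
        fdf = pd.DataFrame.from_dict(feats, orient="index").loc[idx]
        fz = ztransform.apply(fdf) if needed_list else fdf

        for name, (coefs, const, cutoff) in eqs.items():
            lp = np.full(len(idx), const)
            for v, c in coefs.items():
                if v == "cta_score":
                    if cta_z is None:
                        raise ValueError(f"model {name!r} needs the standardized CTA score")
                    lp = lp + c * np.asarray(cta_z, dtype=float)[idx]
                else:
                    lp = lp + c * fz[v].to_numpy()
            probs = 1.0 / (1.0 + np.exp(-lp))
            res = evaluate_at_cutoff(probs, y[idx], cutoff)
            rows.append({"subset": s_idx + 1, "model": name, "n": len(idx), **res})
    return pd.DataFrame(rows)
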