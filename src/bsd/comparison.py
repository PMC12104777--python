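"""Model comparison: model-space enumeration, Bayes factors, family evidence.

A candidate model space is the set of all subsets of candidate peak
bands (2**B models, ordered by binary counting with the first band as
the least-significant bit).  Log Bayes factors are free-energy
differences; the evidence for the presence of a peak is obtained by
averaging free energies over models with and without that peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, ValidationError
from .model import Band, ModelSpec, _check_disjoint

__all__ = [
    "ModelSpace",
    "EvidenceTable",
    "FamilyResult",
    "enumerate_model_space",
    "log_bayes_factor",
    "family_evidence",
    "interpret_bf",
]


@dataclass
class ModelSpace:
    """All models over subsets of candidate bands."""

    candidate_bands: list[Band]
    models: list[ModelSpec]
    presence: np.ndarray  # (n_models, n_bands) boolean

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def model_ids(self) -> list[str]:
        ids = []
        for row in self.presence:
            names = [b.name for b, on in zip(self.candidate_bands, row) if on]
            ids.append("+".join(names) if names else "none")
        return ids


@dataclass
class EvidenceTable:
    """Free energies, subjects (rows) by models (columns)."""

    F: np.ndarray
    subject_ids: list[str]
    model_ids: list[str]

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise DimensionError("evidence table must be 2-D (subjects x models)")
        if self.F.shape != (len(self.subject_ids), len(self.model_ids)):
            raise DimensionError("evidence table shape does not match its labels")
        if not np.all(np.isfinite(self.F)):
            raise ValidationError("evidence table contains non-finite entries")


@dataclass
class FamilyResult:
    """Per-band evidence for peak presence."""

    bands: list[str]
    mean_with: np.ndarray
    mean_without: np.ndarray
    ln_bf: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.mean_with = np.asarray(self.mean_with, dtype=float)
        self.mean_without = np.asarray(self.mean_without, dtype=float)
        self.ln_bf = np.asarray(self.ln_bf, dtype=float)
        if not self.labels:
            self.labels = [interpret_bf(v) for v in self.ln_bf]

    def to_dict(self) -> dict:
        return {
            band: {
                "mean_F_with": float(w),
                "mean_F_without": float(wo),
                "ln_bf": float(b),
                "label": lab,
            }
            for band, w, wo, b, lab in zip(
                self.bands, self.mean_with, self.mean_without, self.ln_bf, self.labels
            )
        }


def enumerate_model_space(candidates: list[Band], base: ModelSpec | None = None) -> ModelSpace:
    """One model per subset of candidate bands, in binary-counting order.

    Model ``j`` contains band ``i`` iff bit ``i`` of ``j`` is set (the
    first band is the least-significant bit); model 0 is aperiodic-only.
    """
    _check_disjoint(candidates)
    base = base or ModelSpec()
    n = len(candidates)
    models, presence = [], []
    for j in range(2 ** n):
        mask = [(j >> i) & 1 == 1 for i in range(n)]
        bands = [b for b, on in zip(candidates, mask) if on]
        models.append(
            ModelSpec(
                bands=bands,
                domain=base.domain,
                filters=list(base.filters),
                condition_design=base.condition_design,
                filter_mode=base.filter_mode,
            )
        )
        presence.append(mask)
    return ModelSpace(
        candidate_bands=list(candidates),
        models=models,
        presence=np.asarray(presence, dtype=bool).reshape(2 ** n, n),
    )


def log_bayes_factor(F1: float, F2: float) -> float:
    """Log Bayes factor of model 1 over model 2, approximated by F1 - F2."""
    if not (np.isfinite(F1) and np.isfinite(F2)):
        raise ValidationError("free energies must be finite")
    return float(F1) - float(F2)


def family_evidence(
    table: EvidenceTable, space: ModelSpace, statistic: str = "mean"
) -> FamilyResult:
    """Evidence for each candidate peak by family-wise free-energy averaging.

    For each band, free energies are averaged over the models containing
    it and over the models lacking it (within subject), then combined
    across subjects with the arithmetic mean (default) or the sum
    (``statistic="sum"``, fixed-effect variant).
    """
    if len(space.candidate_bands) == 0:
        raise ValidationError("family evidence requires at least one candidate band")
    if table.F.shape[1] != space.n_models:
        raise DimensionError("evidence table columns do not match the model space")
    if statistic not in ("mean", "sum"):
        raise ValidationError("statistic must be 'mean' or 'sum'")
    agg = np.mean if statistic == "mean" else np.sum
    mean_with, mean_without, ln_bf = [], [], []
    for i in range(len(space.candidate_bands)):
        has = space.presence[:, i]
        per_subj_with = table.F[:, has].mean(axis=1)
        per_subj_without = table.F[:, ~has].mean(axis=1)
        w = float(agg(per_subj_with))
        wo = float(agg(per_subj_without))
        mean_with.append(w)
        mean_without.append(wo)
        ln_bf.append(w - wo)
    return FamilyResult(
        bands=[b.name for b in space.candidate_bands],
        mean_with=np.asarray(mean_with),
        mean_without=np.asarray(mean_without),
        ln_bf=np.asarray(ln_bf),
    )


# Left-closed interpretation bins for log Bayes factors.
_BF_BINS = (
    (0.0, "negative"),
    (1.0, "weak"),
    (3.0, "positive"),
    (5.0, "strong"),
    (np.inf, "very strong"),
)


def interpret_bf(ln_bf: float) -> str:
    """Qualitative evidence label for a log Bayes factor.

    Bins: < 0 negative; [0, 1) weak; [1, 3) positive; [3, 5) strong;
    >= 5 very strong.
    """
    if not np.isfinite(ln_bf):
        raise ValidationError("log Bayes factor must be finite")
    for edge, label in _BF_BINS:
        if ln_bf < edge:
            return label
    return "very strong"
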