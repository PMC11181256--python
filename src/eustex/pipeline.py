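"""Convenience wiring: lesions -> feature table -> LOOCV -> evaluation."""

from __future__ import annotations

import numpy as np

from .classification import CVResult, FeatureTable, SvmSettings, loocv_svm
from .features import FeatureVector
from .image_io import AnnotatedLesion
from .texture_ggcm import ggcm15
from .texture_glcm import GlcmConfig, glcm48, glcm51

__all__ = ["extract_one", "extract_table", "run_loocv"]

_EXTRACTORS = {
    "GLCM48": lambda lesion, cfg: glcm48(lesion, cfg),
    "GLCM48_PLUS_GLOBAL3": lambda lesion, cfg: glcm51(lesion, cfg),
    "GGCM15": lambda lesion, cfg: ggcm15(lesion),
}


def extract_one(
    lesion: AnnotatedLesion, combination: str, cfg: GlcmConfig | None = None
) -> FeatureVector:
    """Extract one lesion's features for a named combination."""
    try:
        extractor = _EXTRACTORS[combination]
    except KeyError:
        raise ValueError(f"unknown feature combination {combination!r}") from None
    return extractor(lesion, cfg)


def extract_table(
    lesions: list[AnnotatedLesion], combination: str, cfg: GlcmConfig | None = None
) -> FeatureTable:
    """Feature table for a cohort under one feature combination."""
    vectors = [extract_one(lesion, combination, cfg) for lesion in lesions]
    return FeatureTable(
        lesion_ids=tuple(lesion.lesion_id for lesion in lesions),
        matrix=np.vstack([v.values for v in vectors]),
        labels=np.array([lesion.label for lesion in lesions], dtype=np.int64),
        combination_id=combination,
        feature_names=vectors[0].names,
    )


def run_loocv(
    lesions: list[AnnotatedLesion],
    combination: str,
    seed: int = 0,
    settings: SvmSettings = SvmSettings(),
) -> CVResult:
    """Extract features and run leave-one-out SVM in one call."""
    return loocv_svm(extract_table(lesions, combination), seed=seed, settings=settings)
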