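"""End-to-end orchestration: volume -> VTI -> VCM -> features -> classifier.

`extract_lesion_features` runs the whole texture chain for one lesion and
one VTI kind; `run_extract` maps it over a cohort and assembles wide feature
tables; `run_sweep` repeats extract + classify over a quantization-parameter
grid and tabulates mean AUC +/- SD per combination, mirroring the kind of
parameter study used to pick the default quantizations.

Every run can write a JSON sidecar carrying the full parameter provenance
(quantization per kind, displacement, threshold, seeds) so any number in an
output table traces back to its configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CVResult, Dataset, RFParams, cross_validate
from .derivatives import (deriche_second_derivatives, hessian_eigenvalues,
                          sobel_gradient)
from .features import FeatureVector, feature_vector
from .vcm import compute_vcm_stack
from .vector_fields import (DEFAULT_CONFIGS, GRADIENT_KINDS, VTI_KINDS,
                            QuantConfig, build_vti, to_spherical)
from .volume_io import (DEFAULT_AIR_THRESHOLD_HU, ROIMask, Volume,
                        apply_air_threshold)

logger = logging.getLogger("vectex")


@dataclass
class RunConfig:
    """Declarative description of one extraction/classification run."""

    vti_kinds: tuple[str, ...] = VTI_KINDS
    quant: dict[str, QuantConfig] = field(
        default_factory=lambda: dict(DEFAULT_CONFIGS))
    displacement: int = 1
    threshold_hu: float = DEFAULT_AIR_THRESHOLD_HU
    deriche_alpha: float = 1.0
    cv_scheme: str = "twofold_x100"
    n_repeats: int = 100
    k_min: int = 3
    k_max: int = 50
    rf_params: RFParams = field(default_factory=RFParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.vti_kinds:
            raise ValueError("at least one VTI kind is required")
        for kind in self.vti_kinds:
            if kind not in VTI_KINDS:
                raise ValueError(f"unknown VTI kind {kind!r}")
            self.quant.setdefault(kind, DEFAULT_CONFIGS[kind])

    def provenance(self) -> dict:
        return {
            "vti_kinds": list(self.vti_kinds),
            "quant": {k: self.quant[k].to_dict() for k in self.vti_kinds},
            "displacement": self.displacement,
            "threshold_hu": self.threshold_hu,
            "deriche_alpha": self.deriche_alpha,
            "cv_scheme": self.cv_scheme,
            "n_repeats": self.n_repeats,
            "k_min": self.k_min,
            "k_max": self.k_max,
            "rf_params": self.rf_params.to_sklearn(),
            "seed": self.seed,
        }


def extract_lesion_features(volume: Volume, roi: ROIMask, kind: str,
                            cfg: QuantConfig | None = None,
                            displacement: int = 1,
                            threshold_hu: float | None = DEFAULT_AIR_THRESHOLD_HU,
                            deriche_alpha: float = 1.0,
                            lesion_id: str = "lesion",
                            label: int | None = None) -> FeatureVector:
    """The full texture chain for one lesion and one VTI kind.

    Derivative kernels run on the full volume (sub-threshold border voxels
    included); the air threshold only restricts which voxels enter the
    magnitude statistics and the VCM pair accumulation.
    """
    cfg = cfg or DEFAULT_CONFIGS[kind]
    if threshold_hu is not None:
        roi = apply_air_threshold(volume, roi, threshold_hu)
    if kind in GRADIENT_KINDS:
        grad = sobel_gradient(volume)
        sph = to_spherical(*grad.components())
    else:
        eig = hessian_eigenvalues(
            deriche_second_derivatives(volume, alpha=deriche_alpha))
        sph = to_spherical(*eig.components())
    vti = build_vti(kind, sph, cfg, roi)
    stack = compute_vcm_stack(vti, roi, d=displacement)
    return feature_vector(stack, lesion_id=lesion_id, label=label)


def run_extract(config: RunConfig,
                cohort: list[tuple[Volume, ROIMask, int | None]]
                ) -> dict[str, pd.DataFrame]:
    """Extract per-lesion feature tables for every requested VTI kind.

    Returns one wide DataFrame per kind (lesion_id, label, 364 feature
    columns). Per-lesion failures are logged and skipped; an all-failed kind
    raises.
    """
    tables: dict[str, pd.DataFrame] = {}
    for kind in config.vti_kinds:
        rows = []
        for idx, (volume, roi, label) in enumerate(cohort):
            lesion_id = f"lesion_{idx:03d}"
            t0 = time.perf_counter()
            try:
                fv = extract_lesion_features(
                    volume, roi, kind, cfg=config.quant[kind],
                    displacement=config.displacement,
                    threshold_hu=config.threshold_hu,
                    deriche_alpha=config.deriche_alpha,
                    lesion_id=lesion_id, label=label)
            except Exception:
                logger.exception("extraction failed for %s kind %s",
                                 lesion_id, kind)
                continue
            logger.info("extracted %s %s in %.2fs", lesion_id, kind,
                        time.perf_counter() - t0)
            row = {"lesion_id": lesion_id}
            if label is not None:
                row["label"] = label
            row.update(fv.as_dict())
            rows.append(row)
        if not rows:
            raise RuntimeError(f"no lesion could be extracted for kind {kind}")
        tables[kind] = pd.DataFrame(rows)
    return tables


def run_classify(table: pd.DataFrame, config: RunConfig) -> CVResult:
    """Classify one wide feature table under the configured CV scheme."""
    dataset = Dataset.from_dataframe(table)
    return cross_validate(dataset, config.cv_scheme,
                          rf_params=config.rf_params, seed=config.seed,
                          n_repeats=config.n_repeats, k_min=config.k_min,
                          k_max=config.k_max)


def run_sweep(base_config: RunConfig, kind: str,
              grid: list[QuantConfig],
              cohort: list[tuple[Volume, ROIMask, int]]) -> pd.DataFrame:
    """Extract + classify per grid point; tabulate mean AUC +/- SD.

    Returns a DataFrame with one row per quantization combination
    (t_root, q_mag, q_azimuth, q_polar, auc_mean, auc_sd,
    n_selected_features_mean).
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    rows = []
    for cfg in grid:
        config = RunConfig(
            vti_kinds=(kind,), quant={kind: cfg},
            displacement=base_config.displacement,
            threshold_hu=base_config.threshold_hu,
            deriche_alpha=base_config.deriche_alpha,
            cv_scheme=base_config.cv_scheme, n_repeats=base_config.n_repeats,
            k_min=base_config.k_min, k_max=base_config.k_max,
            rf_params=base_config.rf_params, seed=base_config.seed)
        table = run_extract(config, cohort)[kind]
        result = run_classify(table, config)
        rows.append({
            "kind": kind, **cfg.to_dict(),
            "auc_mean": result.summary["auc"]["mean"],
            "auc_sd": result.summary["auc"]["sd"],
            "n_selected_features_mean":
                result.summary["n_selected_features"]["mean"],
        })
    return pd.DataFrame(rows)
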