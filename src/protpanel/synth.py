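"""Synthetic multi-cohort aptamer proteomics studies.

Generates matched case-control expression matrices (serum / CSF / brain)
with the statistical structure the downstream stages assume: case-associated
proteins planted additively on the log2 scale and exponentiated to RFU,
severity-correlated proteins driven by a latent per-case severity,
correlated co-expression blocks, per-batch location/scale effects, and two
assay panel versions sharing an overlapping protein subset.

Default cohort shapes follow the three-cohort study design this pipeline
targets: a serum training set of 572 samples (400 cases / 172 controls),
85 CSF samples, 37 brain samples, and a 932-sample serum replication set;
the two panel generations measure 1129 and 4006 assays with 1047 assays in
common.  All randomness flows through ``numpy.random.default_rng`` (PCG64),
so a fixed seed reproduces the study bit-for-bit on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import ProteinMatrix, SampleMetadata


class ConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass(frozen=True)
class CohortSpec:
    """Shape of one modality's cohort."""

    n_samples: int
    case_fraction: float
    cohort: str = "CohortA"
    panel_version: str = "v2"
    #: multiplier on planted case effects in this modality (1 = full signal)
    attenuation: float = 1.0
    age_mean: float = 66.8
    age_sd: float = 10.4
    age_range: tuple[float, float] = (28.5, 90.9)
    male_fraction: float = 0.57
    #: brain-bank donors carry no MoCA / UPDRS-III scores
    has_clinical: bool = True


@dataclass(frozen=True)
class BatchSpec:
    """Per-batch location shift and scale factor applied on the log2 scale."""

    label: str
    shift: float = 0.0
    scale: float = 1.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic multi-modality case-control study."""

    #: assays per panel version
    n_proteins: dict[str, int] = field(
        default_factory=lambda: {"v2": 1129, "v3": 4006}
    )
    #: size of the cross-version assay intersection
    n_overlap: int = 1047
    modalities: dict[str, CohortSpec] = field(
        default_factory=lambda: {
            "serum": CohortSpec(572, 400 / 572, "CohortA", "v2", 1.0),
            "csf": CohortSpec(85, 70 / 85, "CohortA", "v3", 0.8,
                              age_mean=65.9, age_sd=8.6,
                              age_range=(39.7, 85.1), male_fraction=0.624),
            "brain": CohortSpec(37, 24 / 37, "BrainBank", "v2", 0.6,
                                age_mean=78.9, age_sd=8.2,
                                age_range=(58.0, 91.0), male_fraction=0.784,
                                has_clinical=False),
        }
    )
    #: (protein id, log2 case-control effect); None = 30 overlap proteins
    #: at log2 effect 0.6
    informative_proteins: tuple[tuple[str, float], ...] | None = None
    #: (protein id, slope per unit latent severity)
    severity_proteins: tuple[tuple[str, float], ...] = ()
    #: planted co-expression blocks: (size, within-block correlation)
    module_blocks: tuple[tuple[int, float], ...] = ()
    batch_spec: tuple[BatchSpec, ...] = ()
    #: per-protein Gaussian noise sd on the log2 scale
    noise_sd: float = 0.5
    #: case effects scale as (1 + coupling * latent severity), floored at 0
    severity_effect_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_overlap <= min(self.n_proteins.values()):
            raise ConfigError("n_overlap must be in (0, min panel size]")
        for name, spec in self.modalities.items():
            if not 0 < spec.case_fraction < 1:
                raise ConfigError(f"case_fraction for {name} must be in (0,1)")
            if spec.panel_version not in self.n_proteins:
                raise ConfigError(
                    f"modality {name} uses unknown panel {spec.panel_version!r}"
                )
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        for size, rho in self.module_blocks:
            if not 0 < rho < 1:
                raise ConfigError("within-block correlation must be in (0,1)")
            if size < 2:
                raise ConfigError("module blocks need at least 2 proteins")


# ---------------------------------------------------------------------------
# protein id layout

def panel_proteins(config: SynthConfig, version: str) -> list[str]:
    """Assay ids for one panel version.

    The first ``n_overlap`` ids (``P00001``...) are shared across versions;
    the remainder are version-specific (``V2_0001``... / ``V3_0001``...).
    """
    n = config.n_proteins[version]
    shared = [f"P{i:05d}" for i in range(1, config.n_overlap + 1)]
    extra = [f"{version.upper()}_{i:04d}" for i in range(1, n - config.n_overlap + 1)]
    return shared + extra


def default_informative(config: SynthConfig, n: int = 30, effect: float = 0.6
                        ) -> tuple[tuple[str, float], ...]:
    """The default planted signal: ``n`` shared proteins at one log2 effect."""
    shared = [f"P{i:05d}" for i in range(1, config.n_overlap + 1)]
    return tuple((pid, effect) for pid in shared[:n])


def _resolved_effects(config: SynthConfig) -> dict[str, float]:
    if config.informative_proteins is None:
        return dict(default_informative(config))
    return dict(config.informative_proteins)


def _block_members(config: SynthConfig, version: str) -> list[list[str]]:
    """Assign block members to non-informative panel proteins, back to front."""
    proteins = panel_proteins(config, version)
    taken = set(_resolved_effects(config)) | {p for p, _ in config.severity_proteins}
    free = [p for p in reversed(proteins) if p not in taken]
    blocks: list[list[str]] = []
    pos = 0
    for size, _rho in config.module_blocks:
        if pos + size > len(free):
            raise ConfigError("not enough free proteins for module blocks")
        blocks.append(free[pos:pos + size])
        pos += size
    return blocks


# ---------------------------------------------------------------------------
# generation

_MODALITY_STREAM = {"serum": 1, "csf": 2, "brain": 3}


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    x = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(x, lo, hi)


def _baselines(config: SynthConfig, proteins: list[str]) -> np.ndarray:
    """Per-protein log2 baseline abundance, shared across modalities."""
    rng = np.random.default_rng([config.seed, 997])
    all_ids = sorted(
        set(panel_proteins(config, "v2")) | set(panel_proteins(config, "v3"))
    )
    base = dict(zip(all_ids, rng.normal(10.0, 1.5, len(all_ids))))
    return np.array([base[p] for p in proteins])


def generate_cohort(config: SynthConfig, modality: str,
                    ) -> tuple[ProteinMatrix, SampleMetadata]:
    """Generate one modality's raw-RFU matrix and metadata.

    Case and control counts are fixed (rounded from ``case_fraction``)
    rather than sampled.  The metadata includes a ``latent_severity``
    column (ground truth of the per-case severity construct) so tests can
    check recovery; real metadata would not carry it.
    """
    if modality not in config.modalities:
        raise ConfigError(f"unknown modality {modality!r}")
    spec = config.modalities[modality]
    stream = _MODALITY_STREAM.get(modality, 17)
    rng = np.random.default_rng([config.seed, stream])

    n = spec.n_samples
    n_cases = int(round(spec.case_fraction * n))
    status = np.array(["case"] * n_cases + ["control"] * (n - n_cases))
    rng.shuffle(status)
    is_case = status == "case"

    proteins = panel_proteins(config, spec.panel_version)
    effects = _resolved_effects(config)
    unknown = [p for p in effects if p not in set(panel_proteins(config, "v2"))
               and p not in set(panel_proteins(config, "v3"))]
    unknown += [p for p, _ in config.severity_proteins
                if p not in set(panel_proteins(config, "v2"))
                and p not in set(panel_proteins(config, "v3"))]
    if unknown:
        raise ConfigError(f"effects assigned to unknown protein ids: {unknown}")

    beta = np.array([effects.get(p, 0.0) for p in proteins])
    slope = dict(config.severity_proteins)
    sev_slope = np.array([slope.get(p, 0.0) for p in proteins])

    # latent severity: standard normal per case, zero for controls
    severity = np.where(is_case, rng.normal(0.0, 1.0, n), 0.0)

    log2x = np.tile(_baselines(config, proteins), (n, 1))
    effect_scale = np.maximum(
        1.0 + config.severity_effect_coupling * severity, 0.0
    )
    log2x += np.outer(is_case * effect_scale, beta) * spec.attenuation
    log2x += np.outer(severity, sev_slope)

    prot_index = {p: j for j, p in enumerate(proteins)}
    for (size, rho), members in zip(
        config.module_blocks, _block_members(config, spec.panel_version)
    ):
        lam = config.noise_sd * np.sqrt(rho / (1.0 - rho))
        z = rng.normal(0.0, 1.0, n)
        cols = [prot_index[m] for m in members]
        log2x[:, cols] += np.outer(z, np.full(len(cols), lam))

    log2x += rng.normal(0.0, config.noise_sd, (n, len(proteins)))

    sample_ids = [f"{modality}-{spec.cohort}-S{i:04d}" for i in range(1, n + 1)]

    # clinical covariates
    age = _truncnorm(rng, spec.age_mean, spec.age_sd, *spec.age_range, size=n)
    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    moca = np.full(n, np.nan)
    updrs3 = np.full(n, np.nan)
    if spec.has_clinical:
        # MoCA falls and UPDRS-III rises with latent severity
        moca = np.where(
            is_case,
            24.2 - 2.5 * severity + rng.normal(0, 1.5, n),
            26.8 + rng.normal(0, 2.0, n),
        )
        moca = np.clip(np.round(moca), 0, 30)
        updrs3 = np.where(
            is_case,
            27.8 + 9.0 * severity + rng.normal(0, 4.0, n),
            np.abs(rng.normal(1.8, 2.9, n)),
        )
        updrs3 = np.clip(np.round(updrs3), 0, 100)
    ledd = np.where(is_case, np.clip(rng.normal(353, 264, n), 0, 1450), 0.0)

    if config.batch_spec:
        labels = [b.label for b in config.batch_spec]
        batch = np.array(labels)[rng.integers(0, len(labels), n)]
    else:
        batch = np.full(n, "B1")

    meta = SampleMetadata(pd.DataFrame({
        "sample_id": sample_ids,
        "status": status,
        "age": np.round(age, 1),
        "sex": sex,
        "cohort": spec.cohort,
        "modality": modality,
        "moca": moca,
        "updrs3": updrs3,
        "ledd": np.round(ledd, 1),
        "batch": batch,
        "latent_severity": severity,
    }))

    values = pd.DataFrame(np.exp2(log2x), index=sample_ids, columns=proteins)
    matrix = ProteinMatrix(values, transform_state="raw")
    if config.batch_spec:
        matrix = inject_batch_effects(matrix, meta, config.batch_spec)
    return matrix, meta


def generate_multimodal_study(config: SynthConfig
                              ) -> dict[str, tuple[ProteinMatrix, SampleMetadata]]:
    """Generate every configured modality.

    The same planted proteins carry effects in every modality, scaled by
    each cohort's ``attenuation``; panel membership differs by version
    with the configured overlap.
    """
    return {m: generate_cohort(config, m) for m in config.modalities}


def inject_batch_effects(matrix: ProteinMatrix, metadata: SampleMetadata,
                         batch_spec: tuple[BatchSpec, ...]) -> ProteinMatrix:
    """Apply per-batch location/scale effects on the log2 scale.

    ``log2 x' = shift + scale * log2 x`` per batch; the result is mapped
    back to the matrix's transform state (exponentiated for raw RFU).
    """
    batches = metadata["batch"].astype(str)
    known = {b.label for b in batch_spec}
    missing = sorted(set(batches) - known)
    if missing:
        raise ConfigError(f"batch labels with no spec: {missing}")
    on_log2 = matrix.transform_state == "raw"
    vals = matrix.values.to_numpy(copy=True)
    if on_log2:
        vals = np.log2(vals)
    for b in batch_spec:
        rows = (batches.loc[matrix.sample_ids] == b.label).to_numpy()
        vals[rows] = b.shift + b.scale * vals[rows]
    if on_log2:
        vals = np.exp2(vals)
    out = pd.DataFrame(vals, index=matrix.sample_ids, columns=matrix.protein_ids)
    return ProteinMatrix(out, matrix.transform_state)


def small_config(n_samples: int = 200, case_fraction: float = 0.5,
                 n_proteins: int = 200, n_overlap: int | None = None,
                 seed: int = 0, **kwargs) -> SynthConfig:
    """A reduced single-panel configuration convenient for tests and demos."""
    if n_overlap is None:
        n_overlap = n_proteins
    base = SynthConfig(seed=seed)
    modalities = {
        name: replace(spec, n_samples=n_samples, case_fraction=case_fraction)
        for name, spec in base.modalities.items()
    }
    return SynthConfig(
        n_proteins={"v2": n_proteins, "v3": n_proteins},
        n_overlap=n_overlap,
        modalities=modalities,
        seed=seed,
        **kwargs,
    )
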