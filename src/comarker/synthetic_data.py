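"""Synthetic multi-cohort case-control expression data with planted markers.

The generator emulates the study design this pipeline targets: several
case-control cohorts profiled on different microarray platforms and
drawn from different blood-borne sample types (monocyte, PBMC, whole
blood), with partially overlapping gene panels, several probes per
gene, and a handful of genes truly up-regulated in cases.  The planted
log2 effect of each marker is scaled by a per-sample-type attenuation
multiplier, reproducing the empirical pattern that disease signal in
purified monocytes is diluted in PBMC and diluted much further in
whole blood.

Generative model (everything on the log2 scale; intensities are
therefore log-normal, the standard microarray assumption):

* gene baseline ``b_g ~ Uniform(baseline_log2_range)``, shared by all
  cohorts that profile the gene;
* sample value for gene g: ``b_g + N(0, noise_sd)``, plus
  ``attenuation[sample_type] * base_log2_effect`` for planted markers
  in case samples;
* each gene expands to 1..probes_per_gene probes per platform; a probe
  row is the gene's sample vector plus a per-probe constant offset
  ``N(0, 0.2)`` and iid measurement noise ``N(0, 0.1)`` — distinct but
  correlated rows, which is what probe collapse has to cope with;
* every platform profiles the full shared core plus its own private
  genes, so the intersection of panels across cohorts is exactly the
  core;
* a small fraction of control probes per platform carries no gene
  annotation, exercising annotation-driven probe dropping.

Genes are independent; there are no batch effects, no covariates, and
no dependence structure — see the methods note for what that implies
about test coverage.

Randomness: one :class:`numpy.random.SeedSequence` per run, spawned
into one child per cohort (by cohort index) plus a dedicated child for
the panel/baseline layer, so adding a cohort never perturbs earlier
cohorts' data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import SAMPLE_TYPES, ExpressionDataset, ProbeMap

DEFAULT_SEED = 101

#: fraction of each platform's probes left unannotated
_UNANNOTATED_FRACTION = 0.02
_PROBE_OFFSET_SD = 0.2
_PROBE_NOISE_SD = 0.1


@dataclass
class CohortSpec:
    """One case-control cohort: identity, platform, tissue and sizes."""

    dataset_id: str
    platform_id: str
    sample_type: str
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be >= 1")


@dataclass
class SimConfig:
    """Full parameterization of one synthetic multi-cohort study."""

    seed: int = DEFAULT_SEED
    cohorts: list[CohortSpec] = field(default_factory=list)
    n_genes: int = 2000
    panel_overlap: float = 0.8
    probes_per_gene: tuple[int, int] = (1, 3)
    planted_markers: list[tuple[str, float]] = field(default_factory=list)
    attenuation: dict[str, float] = field(
        default_factory=lambda: {"monocyte": 1.0, "pbmc": 0.6, "whole_blood": 0.15}
    )
    noise_sd: float = 0.25
    baseline_log2_range: tuple[float, float] = (4.0, 12.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.panel_overlap <= 1.0):
            raise ValueError("panel_overlap must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if any(a <= 0 for a in self.attenuation.values()):
            raise ValueError("attenuation multipliers must be > 0")
        lo, hi = self.probes_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("probes_per_gene range invalid")
        core = set(core_gene_symbols(self.n_genes))
        missing = [g for g, _ in self.planted_markers if g not in core]
        if missing:
            raise ValueError(
                f"planted genes not in the shared core: {missing[:5]} "
                "(a gene absent from the core could never be a common marker)"
            )

    @property
    def small_n_cohorts(self) -> list[str]:
        """Cohorts with fewer than 2 cases (t-test undefined there)."""
        return [c.dataset_id for c in self.cohorts if c.n_case < 2]


@dataclass
class GroundTruth:
    """What was planted: the marker set and per-cohort expected effects."""

    planted_genes: frozenset[str]
    #: (gene, dataset_id) -> expected log2 case-control difference
    expected_log2_effects: dict[tuple[str, str], float]

    def expected_effect(self, gene: str, dataset_id: str) -> float:
        return self.expected_log2_effects[(gene, dataset_id)]


def core_gene_symbols(n_genes: int) -> list[str]:
    """Symbols of the shared core panel, lexicographically ordered."""
    return [f"G{i:05d}" for i in range(n_genes)]


def default_study_config(
    n_genes: int = 2000,
    n_planted: int = 15,
    effect_range: tuple[float, float] = (1.5, 3.0),
    seed: int = DEFAULT_SEED,
) -> SimConfig:
    """The canonical four-cohort study design.

    Four cohorts over three blood-borne sample types with case/control
    sizes 5/5 (monocyte), 61/20 (PBMC), 99/30 and 157/20 (whole
    blood), on three platforms (the two whole-blood cohorts sharing
    one).  Attenuation defaults 1.0 / 0.6 / 0.15 give the
    monocyte > PBMC > whole-blood fold-change ladder seen in real
    interferon-pathway markers.  Planted effects are evenly spaced
    across ``effect_range`` (log2) over the first ``n_planted`` core
    genes.
    """
    cohorts = [
        CohortSpec("SIM1", "PLAT96", "monocyte", 5, 5),
        CohortSpec("SIM2", "PLAT570", "pbmc", 61, 20),
        CohortSpec("SIM3", "PLAT570B", "whole_blood", 99, 30),
        CohortSpec("SIM4", "PLAT10558", "whole_blood", 157, 20),
    ]
    symbols = core_gene_symbols(n_genes)
    if n_planted > 0:
        effects = np.linspace(effect_range[0], effect_range[1], n_planted)
        planted = [(symbols[i], float(effects[i])) for i in range(n_planted)]
    else:
        planted = []
    return SimConfig(seed=seed, cohorts=cohorts, n_genes=n_genes, planted_markers=planted)


def _platform_seed(seed: int, platform_id: str) -> np.random.SeedSequence:
    """Deterministic per-platform entropy, independent of cohort order."""
    digest = hashlib.sha256(platform_id.encode()).digest()
    return np.random.SeedSequence([seed, int.from_bytes(digest[:4], "big")])


def _build_platform(
    cfg: SimConfig, platform_id: str, core: list[str]
) -> tuple[list[str], ProbeMap, dict[str, float]]:
    """Panel, probe map and probe offsets for one platform.

    The panel is the full shared core plus platform-private genes, so
    intersecting panels over any set of platforms recovers exactly the
    core.  Private gene count follows ``panel_overlap``: the core is
    that fraction of the platform's annotated panel.
    """
    rng = np.random.default_rng(_platform_seed(cfg.seed, platform_id))
    n_private = int(round(cfg.n_genes * (1.0 / cfg.panel_overlap - 1.0)))
    private = [f"P{platform_id}_{i:05d}" for i in range(n_private)]
    panel = core + private
    lo, hi = cfg.probes_per_gene
    entries: dict[str, str] = {}
    offsets: dict[str, float] = {}
    for gene in panel:
        k = int(rng.integers(lo, hi + 1))
        for j in range(k):
            probe = f"{platform_id}:{gene}_at{j}"
            entries[probe] = gene
            offsets[probe] = float(rng.normal(0.0, _PROBE_OFFSET_SD))
    n_junk = int(round(len(entries) * _UNANNOTATED_FRACTION))
    junk = [f"{platform_id}:AFFX_ctrl{i}" for i in range(n_junk)]
    for probe in junk:
        offsets[probe] = float(rng.normal(0.0, _PROBE_OFFSET_SD))
    return panel, ProbeMap(platform_id=platform_id, entries=entries), offsets


def generate_multidataset(
    cfg: SimConfig,
) -> tuple[list[ExpressionDataset], list[ProbeMap], GroundTruth]:
    """Simulate every cohort in ``cfg``; fully reproducible from its seed.

    Returns the probe-level datasets (probe rows shuffled per platform,
    as deposited files never arrive gene-sorted), one probe map per
    distinct platform, and the ground truth of planted effects.
    """
    if not cfg.cohorts:
        raise ValueError("config has no cohorts")
    ids = [c.dataset_id for c in cfg.cohorts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset_id in config")

    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(cfg.cohorts) + 1)
    base_rng = np.random.default_rng(children[0])

    core = core_gene_symbols(cfg.n_genes)
    lo, hi = cfg.baseline_log2_range
    baselines = {g: float(base_rng.uniform(lo, hi)) for g in core}
    effects = dict(cfg.planted_markers)

    platforms: dict[str, tuple[list[str], ProbeMap, dict[str, float]]] = {}
    for spec in cfg.cohorts:
        if spec.platform_id not in platforms:
            platforms[spec.platform_id] = _build_platform(cfg, spec.platform_id, core)

    datasets: list[ExpressionDataset] = []
    truth_effects: dict[tuple[str, str], float] = {}
    for ci, spec in enumerate(cfg.cohorts):
        rng = np.random.default_rng(children[ci + 1])
        panel, pmap, offsets = platforms[spec.platform_id]
        atten = cfg.attenuation.get(spec.sample_type, 1.0)
        n = spec.n_case + spec.n_control
        case_mask = np.r_[np.ones(spec.n_case, bool), np.zeros(spec.n_control, bool)]

        # per-gene sample values on log2 scale
        gene_values: dict[str, np.ndarray] = {}
        for gene in panel:
            b = baselines.get(gene)
            if b is None:  # platform-private gene: baseline from platform seed space
                b = float(rng.uniform(lo, hi))
            vals = b + rng.normal(0.0, cfg.noise_sd, size=n)
            if gene in effects:
                delta = atten * effects[gene]
                vals = vals + np.where(case_mask, delta, 0.0)
                truth_effects[(gene, spec.dataset_id)] = delta
            gene_values[gene] = vals

        probe_ids = list(offsets.keys())
        rng.shuffle(probe_ids)
        values = np.empty((len(probe_ids), n))
        for r, probe in enumerate(probe_ids):
            gene = pmap.entries.get(probe)
            base = gene_values[gene] if gene is not None else rng.uniform(lo, hi) + np.zeros(n)
            values[r] = base + offsets[probe] + rng.normal(0.0, _PROBE_NOISE_SD, size=n)

        sample_ids = [f"{spec.dataset_id}_S{j:03d}" for j in range(n)]
        labels = ["case" if m else "control" for m in case_mask]
        datasets.append(
            ExpressionDataset(
                dataset_id=spec.dataset_id,
                platform_id=spec.platform_id,
                sample_type=spec.sample_type,
                probe_ids=probe_ids,
                sample_ids=sample_ids,
                labels=labels,
                values=values,
            )
        )

    probe_maps = [platforms[pid][1] for pid in dict.fromkeys(c.platform_id for c in cfg.cohorts)]
    truth = GroundTruth(
        planted_genes=frozenset(g for g, _ in cfg.planted_markers),
        expected_log2_effects=truth_effects,
    )
    return datasets, probe_maps, truth


def config_to_dict(cfg: SimConfig) -> dict:
    """Plain-dict form of a config (for the YAML the CLI writes)."""
    d = asdict(cfg)
    d["probes_per_gene"] = list(cfg.probes_per_gene)
    d["baseline_log2_range"] = list(cfg.baseline_log2_range)
    d["planted_markers"] = [[g, e] for g, e in cfg.planted_markers]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["cohorts"] = [CohortSpec(**c) for c in d.get("cohorts", [])]
    if "probes_per_gene" in d:
        d["probes_per_gene"] = tuple(d["probes_per_gene"])
    if "baseline_log2_range" in d:
        d["baseline_log2_range"] = tuple(d["baseline_log2_range"])
    if "planted_markers" in d:
        d["planted_markers"] = [(g, float(e)) for g, e in d["planted_markers"]]
    return SimConfig(**d)
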