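"""Seeded synthetic data for the paired red/white organizer screen.

The generator emulates the experimental design of the screen: two capture
methods (laser capture microdissection, manual dissection), three biological
replicate pairs per method, and for each pair one "red" sample of labelled
organizer-resident cells from the anterior primitive streak (PS) and one
"white" sample of adjacent unlabelled neural-plate / paraxial-mesoderm cells.
Counts are negative binomial with per-sample library-size factors,
method-specific dispersion, Bernoulli dropout (degraded laser-capture RNA)
and linear compartment cross-contamination (coarse manual dissection).

Planted gene classes drive the downstream filters:

``msz_marker``
    expressed by resident cells only; anterior-PS restricted; off at
    gastrulation, on from the initiation of elongation onward.  These are
    the genes the full pipeline should recover.
``gastrulation_transient``
    red-enriched and anterior-PS restricted but already on during
    gastrulation — fails marker criterion (i) only.
``msz_like_transient``
    passes criteria (i)-(ii) but switches off at the last elongation
    timepoint — fails criterion (iii) only.
``anteriorPS_nonspecific``
    anterior-PS plus one disallowed region — removed by the regional screen.
``neural`` / ``paraxial`` / ``housekeeping``
    expressed in the white compartment (and, for housekeeping, everywhere);
    never red-enriched.
``silent``
    all-zero filler.

Sampling is by inverse-CDF on seeded uniform draws whose layout depends only
on the design dimensions, never on the noise parameters.  Identical
config+seed therefore reproduces identical output bit for bit on any
platform, and two configs differing only in a noise parameter (for example a
contamination sweep) share their underlying randomness, so planted-signal
recovery responds to the parameter monotonically rather than through
resampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Fixed six-region vocabulary of the localization screen.
REGIONS: tuple[str, ...] = (
    "anterior_PS",
    "anterior_midline",
    "caudal_neural",
    "anterior_neural",
    "caudal_PS",
    "non_neural_ectoderm",
)

#: Regions whose detection disqualifies a candidate in the regional screen.
DISALLOWED_REGIONS: tuple[str, ...] = (
    "caudal_neural",
    "anterior_neural",
    "caudal_PS",
    "non_neural_ectoderm",
)

#: Fixed stage vocabulary; elongation carries >= 1 timepoints.
STAGES: tuple[str, ...] = ("gastrulation", "initiation", "elongation")

GENE_CLASSES: tuple[str, ...] = (
    "msz_marker",
    "neural",
    "paraxial",
    "housekeeping",
    "gastrulation_transient",
    "anteriorPS_nonspecific",
    "msz_like_transient",
    "silent",
)

#: Default identifiers for the planted markers, after the four genes the
#: screen is built to find (WIF1, PTGDS, ThPO, UCKL1 orthologue-like signals).
MARKER_GENE_NAMES: tuple[str, ...] = (
    "WIF1_like",
    "PTGDS_like",
    "THPO_like",
    "UCKL1_like",
)

DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "msz_marker": 4,
    "neural": 50,
    "paraxial": 50,
    "housekeeping": 50,
    "gastrulation_transient": 50,
    "anteriorPS_nonspecific": 50,
    "msz_like_transient": 50,
}

#: White-compartment tissues sampled in the unlabelled dissections.
_WHITE_TISSUE_REGIONS = frozenset({"caudal_neural", "anterior_neural", "caudal_PS"})


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic paired-sample screen.

    Expression is in raw count units; ``base_mean`` is the expected count of
    an "on" gene in a library of scale factor 1.  Normalization is the
    scoring stage's job.
    """

    n_genes: int = 1000
    class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    n_replicates_per_method: int = 3
    methods: tuple[str, ...] = ("laser", "manual")
    base_mean: float = 100.0
    dispersion_by_method: Mapping[str, float] = field(
        default_factory=lambda: {"laser": 0.4, "manual": 0.15}
    )
    dropout_prob_by_method: Mapping[str, float] = field(
        default_factory=lambda: {"laser": 0.2, "manual": 0.0}
    )
    contamination_by_method: Mapping[str, float] = field(
        default_factory=lambda: {"laser": 0.0, "manual": 0.1}
    )
    library_size_mean: float = 1.0
    library_size_cv: float = 0.3
    # Laser capture yields shallower libraries than manual dissection.
    library_scale_by_method: Mapping[str, float] = field(
        default_factory=lambda: {"laser": 0.5, "manual": 1.0}
    )
    n_elongation_timepoints: int = 3
    # Optional additive Gaussian noise on the regional/stage tables
    # (truncated at zero); 0 keeps the RT-PCR/in situ readouts noise-free.
    table_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field if invalid."""
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_replicates_per_method <= 0:
            raise ValueError(
                "n_replicates_per_method must be positive, got "
                f"{self.n_replicates_per_method}"
            )
        if not self.methods:
            raise ValueError("methods must be a non-empty list")
        if len(set(self.methods)) != len(self.methods):
            raise ValueError("methods must be unique")
        for cls, n in self.class_counts.items():
            if cls not in GENE_CLASSES:
                raise ValueError(f"class_counts: unknown gene class {cls!r}")
            if n < 0:
                raise ValueError(f"class_counts[{cls!r}] must be >= 0, got {n}")
        if sum(self.class_counts.values()) > self.n_genes:
            raise ValueError(
                "class_counts sum to "
                f"{sum(self.class_counts.values())} > n_genes={self.n_genes}"
            )
        if self.base_mean <= 0:
            raise ValueError(f"base_mean must be > 0, got {self.base_mean}")
        if self.library_size_mean <= 0:
            raise ValueError(
                f"library_size_mean must be > 0, got {self.library_size_mean}"
            )
        if self.library_size_cv <= 0:
            raise ValueError(
                f"library_size_cv must be > 0, got {self.library_size_cv}"
            )
        if self.n_elongation_timepoints < 1:
            raise ValueError(
                "n_elongation_timepoints must be >= 1, got "
                f"{self.n_elongation_timepoints}"
            )
        if self.table_noise_sd < 0:
            raise ValueError(
                f"table_noise_sd must be >= 0, got {self.table_noise_sd}"
            )
        for name, mapping, lo_ok in (
            ("dispersion_by_method", self.dispersion_by_method, True),
            ("dropout_prob_by_method", self.dropout_prob_by_method, True),
            ("contamination_by_method", self.contamination_by_method, True),
            ("library_scale_by_method", self.library_scale_by_method, False),
        ):
            for m in self.methods:
                if m not in mapping:
                    raise ValueError(f"{name} is missing method {m!r}")
        for m in self.methods:
            if self.dispersion_by_method[m] < 0:
                raise ValueError(
                    f"dispersion_by_method[{m!r}] must be >= 0, got "
                    f"{self.dispersion_by_method[m]}"
                )
            if not 0.0 <= self.dropout_prob_by_method[m] <= 1.0:
                raise ValueError(
                    f"dropout_prob_by_method[{m!r}] must be in [0, 1], got "
                    f"{self.dropout_prob_by_method[m]}"
                )
            if not 0.0 <= self.contamination_by_method[m] <= 1.0:
                raise ValueError(
                    f"contamination_by_method[{m!r}] must be in [0, 1], got "
                    f"{self.contamination_by_method[m]}"
                )
            if self.library_scale_by_method[m] <= 0:
                raise ValueError(
                    f"library_scale_by_method[{m!r}] must be > 0, got "
                    f"{self.library_scale_by_method[m]}"
                )

    def replace(self, **changes) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


class SyntheticDataset(NamedTuple):
    """The five tables produced by :func:`generate_dataset`."""

    counts: pd.DataFrame  # gene x sample, int64
    samples: pd.DataFrame  # sample_id, color, method, replicate
    regional: pd.DataFrame  # gene x six regions, float
    stages: pd.DataFrame  # long: gene_id, stage, timepoint, region, value
    truth: pd.DataFrame  # gene_id, gene_class


def _gene_table(config: SimulationConfig) -> pd.DataFrame:
    """Assign ids, classes and per-class attributes to every gene.

    Returns a frame with columns gene_id, gene_class, extra_region (the
    second "on" region of anteriorPS_nonspecific genes, empty otherwise).
    """
    rows: list[tuple[str, str, str]] = []
    for cls in GENE_CLASSES:
        n = config.class_counts.get(cls, 0)
        for i in range(n):
            if cls == "msz_marker" and i < len(MARKER_GENE_NAMES):
                gid = MARKER_GENE_NAMES[i]
            else:
                gid = f"{cls}_{i:04d}"
            extra = ""
            if cls == "anteriorPS_nonspecific":
                extra = DISALLOWED_REGIONS[i % len(DISALLOWED_REGIONS)]
            rows.append((gid, cls, extra))
    n_silent = config.n_genes - len(rows)
    start = config.class_counts.get("silent", 0)
    for i in range(n_silent):
        rows.append((f"silent_{start + i:04d}", "silent", ""))
    return pd.DataFrame(rows, columns=["gene_id", "gene_class", "extra_region"])


def _compartment_profiles(
    genes: pd.DataFrame, base_mean: float
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected abundance of each gene in the red (resident
    anterior-PS) and white (neighbouring neural/paraxial) compartments."""
    cls = genes["gene_class"].to_numpy()
    red = np.zeros(len(genes))
    white = np.zeros(len(genes))
    red_on = np.isin(
        cls,
        [
            "msz_marker",
            "housekeeping",
            "gastrulation_transient",
            "anteriorPS_nonspecific",
            "msz_like_transient",
        ],
    )
    white_on = np.isin(cls, ["neural", "paraxial", "housekeeping"])
    # A nonspecific gene leaks into the white sample only if its extra
    # region is a tissue the white dissection actually contains.
    nonspecific_leak = (cls == "anteriorPS_nonspecific") & genes[
        "extra_region"
    ].isin(_WHITE_TISSUE_REGIONS).to_numpy()
    red[red_on] = base_mean
    white[white_on | nonspecific_leak] = base_mean
    return red, white


def _regional_on_sets(genes: pd.DataFrame) -> list[frozenset[str]]:
    """Region set in which each gene is expressed (stage-agnostic screen)."""
    out = []
    for cls, extra in zip(genes["gene_class"], genes["extra_region"]):
        if cls in ("msz_marker", "gastrulation_transient", "msz_like_transient"):
            on = {"anterior_PS"}
        elif cls == "anteriorPS_nonspecific":
            on = {"anterior_PS", extra}
        elif cls == "neural":
            on = {"caudal_neural", "anterior_neural"}
        elif cls == "paraxial":
            on = {"caudal_PS"}
        elif cls == "housekeeping":
            on = set(REGIONS)
        else:  # silent
            on = set()
        out.append(frozenset(on))
    return out


def _stage_on_set(
    cls: str, extra: str, stage: str, timepoint: int, n_elongation: int
) -> frozenset[str]:
    """Regions in which a gene of class ``cls`` is on at a given stage."""
    if cls == "housekeeping":
        return frozenset(REGIONS)
    if cls == "silent":
        return frozenset()
    if cls == "msz_marker":
        return frozenset() if stage == "gastrulation" else frozenset({"anterior_PS"})
    if cls == "msz_like_transient":
        # Passes criteria (i)-(ii); off at the last elongation timepoint.
        if stage == "gastrulation":
            return frozenset()
        if stage == "elongation" and timepoint == n_elongation:
            return frozenset()
        return frozenset({"anterior_PS"})
    if cls == "gastrulation_transient":
        return frozenset({"anterior_PS"})
    if cls == "anteriorPS_nonspecific":
        if stage == "gastrulation":
            return frozenset()
        return frozenset({"anterior_PS", extra})
    if cls == "neural":
        if stage == "gastrulation":
            return frozenset()
        return frozenset({"caudal_neural", "anterior_neural"})
    if cls == "paraxial":
        if stage == "gastrulation":
            return frozenset()
        return frozenset({"caudal_PS"})
    raise ValueError(f"unknown gene class {cls!r}")


def _stage_timepoints(config: SimulationConfig) -> list[tuple[str, int]]:
    tps = [("gastrulation", 1), ("initiation", 1)]
    tps.extend(("elongation", t) for t in range(1, config.n_elongation_timepoints + 1))
    return tps


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for method in config.methods:
        for rep in range(1, config.n_replicates_per_method + 1):
            for color in ("red", "white"):
                rows.append((f"{method}_rep{rep}_{color}", color, method, rep))
    return pd.DataFrame(rows, columns=["sample_id", "color", "method", "replicate"])


def _nb_quantile(u: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Inverse CDF of NB(mean=mu, var=mu+alpha*mu^2) at uniform draws ``u``.

    alpha == 0 falls back to Poisson; mu == 0 yields 0.  Monotone
    non-decreasing in mu at fixed u, which is what makes common-random-number
    parameter sweeps well behaved.
    """
    u, mu, alpha = np.broadcast_arrays(u, mu, alpha)
    counts = np.zeros(u.shape, dtype=np.int64)
    pos = mu > 0
    nb = pos & (alpha > 0)
    if np.any(nb):
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        counts[nb] = stats.nbinom.ppf(u[nb], size, p).astype(np.int64)
    po = pos & (alpha == 0)
    if np.any(po):
        counts[po] = stats.poisson.ppf(u[po], mu[po]).astype(np.int64)
    return counts


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate counts, sample sheet, regional/stage tables and truth labels.

    Red-sample abundance of each gene is ``(1-lambda) * red_profile +
    lambda * white_profile`` with lambda the method's contamination fraction
    (symmetric for white samples); the expected count is that abundance times
    the sample's library-size factor, drawn Gamma with the configured mean and
    CV.  Counts are negative binomial with the method's dispersion; dropout
    then zeroes each entry independently with the method's probability.
    """
    config.validate()
    genes = _gene_table(config)
    samples = _sample_sheet(config)
    red_prof, white_prof = _compartment_profiles(genes, config.base_mean)

    rng = np.random.default_rng(config.seed)
    n_genes, n_samples = len(genes), len(samples)
    # Fixed draw order, with shapes independent of the noise parameters.
    u_lib = rng.random(n_samples)
    u_counts = rng.random((n_genes, n_samples))
    u_drop = rng.random((n_genes, n_samples))

    cv2 = config.library_size_cv**2
    lib_mean = np.array(
        [
            config.library_size_mean * config.library_scale_by_method[m]
            for m in samples["method"]
        ]
    )
    lib = stats.gamma.ppf(u_lib, a=1.0 / cv2, scale=lib_mean * cv2)

    mu = np.empty((n_genes, n_samples))
    alpha = np.empty(n_samples)
    drop_p = np.empty(n_samples)
    for j, row in samples.iterrows():
        lam = config.contamination_by_method[row["method"]]
        if row["color"] == "red":
            abundance = (1.0 - lam) * red_prof + lam * white_prof
        else:
            abundance = (1.0 - lam) * white_prof + lam * red_prof
        mu[:, j] = abundance * lib[j]
        alpha[j] = config.dispersion_by_method[row["method"]]
        drop_p[j] = config.dropout_prob_by_method[row["method"]]

    counts = _nb_quantile(u_counts, mu, alpha[None, :])
    counts[u_drop < drop_p[None, :]] = 0

    counts_df = pd.DataFrame(
        counts, index=pd.Index(genes["gene_id"], name="gene_id"),
        columns=samples["sample_id"].to_list(),
    )

    regional = np.zeros((n_genes, len(REGIONS)))
    for i, on in enumerate(_regional_on_sets(genes)):
        for r in on:
            regional[i, REGIONS.index(r)] = config.base_mean
    regional_df = pd.DataFrame(
        regional, index=pd.Index(genes["gene_id"], name="gene_id"),
        columns=list(REGIONS),
    )

    tps = _stage_timepoints(config)
    stage_rows = []
    for gid, cls, extra in zip(
        genes["gene_id"], genes["gene_class"], genes["extra_region"]
    ):
        for stage, tp in tps:
            on = _stage_on_set(cls, extra, stage, tp, config.n_elongation_timepoints)
            for r in REGIONS:
                stage_rows.append(
                    (gid, stage, tp, r, config.base_mean if r in on else 0.0)
                )
    stages_df = pd.DataFrame(
        stage_rows, columns=["gene_id", "stage", "timepoint", "region", "value"]
    )

    if config.table_noise_sd > 0:
        regional_df.iloc[:, :] = np.maximum(
            regional_df.to_numpy()
            + rng.normal(0, config.table_noise_sd, regional_df.shape),
            0.0,
        )
        stages_df["value"] = np.maximum(
            stages_df["value"].to_numpy()
            + rng.normal(0, config.table_noise_sd, len(stages_df)),
            0.0,
        )

    truth = genes[["gene_id", "gene_class"]].copy()
    return SyntheticDataset(counts_df, samples, regional_df, stages_df, truth)
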