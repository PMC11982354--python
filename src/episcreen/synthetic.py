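"""Synthetic inputs with known ground truth for every pipeline stage.

Three families of generators define the study conditions the package is
tested under:

* a paired-style discovery cohort (default 31 tumor vs 12 normal samples)
  with negative-binomial RNA-seq counts and Beta-distributed methylation
  values, in which a chosen subset of genes is planted as simultaneously
  hypermethylated (beta-scale shift) and down-expressed (negative log2FC);
* survival records drawn from an exponential proportional-hazards model
  with independent exponential censoring;
* two-channel fluorescence scenes (nuclei + lipid-droplet puncta rendered
  as anti-aliased disks over a cytoplasm disk) and stained-area images
  with an exactly known covered pixel fraction.

All generators are deterministic for a fixed seed; independent substreams
are derived from a single master seed by fixed offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .methylome import BetaMatrix, REGION_CLASSES
from .transcriptome import CountMatrix

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "SurvivalSpec",
    "ImageSceneSpec",
    "StainSpec",
    "SceneTruth",
    "gen_cohort",
    "gen_survival",
    "gen_fluor_scene",
    "gen_stained_image",
    "write_cohort",
    "write_survival",
    "write_scene",
]

# fixed substream offsets off the master seed
_SUB_COUNTS = 11
_SUB_BETA = 23
_SUB_SURV = 37
_SUB_SCENE = 53
_SUB_STAIN = 71


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic discovery cohort.

    Defaults emulate a breast-tumor methylome/transcriptome cohort of
    31 tumor and 12 normal specimens with a modest set of planted
    tumor-suppressor-like genes (hypermethylated by ``planted_meth_delta``
    on the beta scale, down-expressed by ``planted_expr_lfc`` log2 units).
    """

    n_genes: int = 2000
    probes_per_gene: tuple[int, int] = (3, 8)
    n_tumor: int = 31
    n_normal: int = 12
    n_planted: int = 40
    planted_meth_delta: float = 0.25
    planted_expr_lfc: float = -2.0
    nb_dispersion: float = 0.2
    baseline_log_mean_range: tuple[float, float] = (3.0, 9.0)
    # (low-mode mean range, high-mode mean range, weight of low mode)
    baseline_beta_mode: tuple[tuple[float, float], tuple[float, float], float] = (
        (0.05, 0.30),
        (0.60, 0.95),
        0.5,
    )
    beta_precision: float = 30.0
    #: pin the planted gene identities (e.g. to share truth across two
    #: cohorts emulating discovery + validation); None draws them at random
    planted_genes: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted exceeds n_genes")
        if self.planted_genes is not None and len(self.planted_genes) != self.n_planted:
            raise ValueError("planted_genes length must equal n_planted")
        if min(self.n_genes, self.n_tumor, self.n_normal, self.n_planted) < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.planted_meth_delta < 1:
            raise ValueError("planted_meth_delta must lie in [0, 1)")
        if self.planted_meth_delta > 0.90:
            raise ValueError(
                "planted_meth_delta pushes tumor beta means past 1 before clipping"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be positive")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("probes_per_gene must be a valid positive range")


@dataclass
class CohortTruth:
    """Planted genes with their true effects."""

    table: pd.DataFrame  # columns: gene, meth_delta, expr_lfc

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def gen_cohort(spec: CohortSpec):
    """Generate (CountMatrix, BetaMatrix, annotation, sample sheet, CohortTruth)."""
    spec.validate()
    rng_c = np.random.default_rng(spec.seed + _SUB_COUNTS)
    rng_b = np.random.default_rng(spec.seed + _SUB_BETA)

    genes = [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]
    samples = [f"T{i:02d}" for i in range(1, spec.n_tumor + 1)] + [
        f"N{i:02d}" for i in range(1, spec.n_normal + 1)
    ]
    groups = pd.Series(
        ["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal, index=samples
    )
    n_pairs = min(spec.n_tumor, spec.n_normal)
    patients = pd.Series(pd.NA, index=samples, dtype="object")
    for i in range(n_pairs):
        patients[f"T{i + 1:02d}"] = f"P{i + 1:02d}"
        patients[f"N{i + 1:02d}"] = f"P{i + 1:02d}"

    if spec.planted_genes is not None:
        lookup = {g: i for i, g in enumerate(genes)}
        try:
            planted_idx = np.array([lookup[g] for g in spec.planted_genes], dtype=int)
        except KeyError as exc:
            raise ValueError(f"planted gene {exc} not in the gene universe") from exc
    elif spec.n_planted:
        planted_idx = rng_c.choice(spec.n_genes, size=spec.n_planted, replace=False)
    else:
        planted_idx = np.array([], dtype=int)
    planted = np.zeros(spec.n_genes, dtype=bool)
    planted[planted_idx] = True

    # --- expression: negative binomial, gene-specific log2 mean -------------
    lo, hi = spec.baseline_log_mean_range
    log_mu = rng_c.uniform(lo, hi, size=spec.n_genes)
    mu = np.exp2(log_mu)
    mu_mat = np.tile(mu[:, None], (1, len(samples)))
    tumor_cols = np.arange(spec.n_tumor)
    mu_mat[np.ix_(planted_idx, tumor_cols)] *= 2.0 ** spec.planted_expr_lfc
    r = 1.0 / spec.nb_dispersion  # NB size so that var = mu + disp * mu^2
    p_nb = r / (r + mu_mat)
    counts = rng_c.negative_binomial(r, p_nb)
    lengths = pd.Series(rng_c.integers(500, 5001, size=spec.n_genes), index=genes)
    count_matrix = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), lengths, groups, patients
    )

    # --- methylation: per-gene bimodal baseline, Beta(mean, precision) ------
    (lo_lo, lo_hi), (hi_lo, hi_hi), w_low = spec.baseline_beta_mode
    low = rng_b.random(spec.n_genes) < w_low
    gene_mean = np.where(
        low,
        rng_b.uniform(lo_lo, lo_hi, size=spec.n_genes),
        rng_b.uniform(hi_lo, hi_hi, size=spec.n_genes),
    )
    # planted genes start low enough that the tumor shift stays inside [0,1]
    if spec.n_planted:
        upper = min(0.95, 0.96 - spec.planted_meth_delta)
        gene_mean[planted_idx] = rng_b.uniform(0.08, upper, size=spec.n_planted)

    n_probes = rng_b.integers(
        spec.probes_per_gene[0], spec.probes_per_gene[1] + 1, size=spec.n_genes
    )
    probe_gene = np.repeat(np.arange(spec.n_genes), n_probes)
    total_probes = int(n_probes.sum())
    jitter = rng_b.uniform(-0.03, 0.03, size=total_probes)
    probe_mean = np.clip(gene_mean[probe_gene] + jitter, 0.01, 0.99)
    probe_planted = planted[probe_gene]
    probe_mean[probe_planted] = np.minimum(
        probe_mean[probe_planted], 0.98 - spec.planted_meth_delta
    )
    mean_mat = np.tile(probe_mean[:, None], (1, len(samples)))
    mean_mat[np.ix_(np.flatnonzero(probe_planted), tumor_cols)] += (
        spec.planted_meth_delta
    )
    np.clip(mean_mat, 0.01, 0.99, out=mean_mat)
    kappa = spec.beta_precision
    beta_vals = rng_b.beta(mean_mat * kappa, (1 - mean_mat) * kappa)

    probe_ids = [f"cg{i:08d}" for i in range(1, total_probes + 1)]
    annotation = pd.DataFrame(
        {
            "gene": [genes[g] for g in probe_gene],
            "chrom": rng_b.choice([f"chr{c}" for c in range(1, 23)], size=total_probes),
            "pos": rng_b.integers(1, 2_000_000_00, size=total_probes),
            "region": rng_b.choice(REGION_CLASSES, size=total_probes),
        },
        index=pd.Index(probe_ids, name="probe"),
    )
    beta_matrix = BetaMatrix(
        pd.DataFrame(beta_vals, index=probe_ids, columns=samples),
        annotation,
        groups,
        patients,
    )

    sheet = pd.DataFrame(
        {"sample": samples, "group": groups.values, "patient": patients.values}
    )
    truth = CohortTruth(
        pd.DataFrame(
            {
                "gene": [genes[i] for i in sorted(planted_idx)],
                "meth_delta": spec.planted_meth_delta,
                "expr_lfc": spec.planted_expr_lfc,
            }
        )
        if spec.n_planted
        else pd.DataFrame(columns=["gene", "meth_delta", "expr_lfc"])
    )
    return count_matrix, beta_matrix, annotation, sheet, truth


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential proportional-hazards cohort with independent censoring.

    ``marker_distribution`` is ('normal', mu, sd), ('uniform', a, b) or
    ('bernoulli', p). The hazard is
    h(t | x) = baseline_hazard * exp(log_hr_per_unit * x); censoring times
    are exponential with the rate that yields the stated censoring fraction
    under the baseline hazard.
    """

    n_patients: int = 200
    marker_distribution: tuple = ("normal", 0.0, 1.0)
    log_hr_per_unit: float = 1.0
    baseline_hazard: float = 0.02  # events per month
    censoring_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.marker_distribution[0] not in {"normal", "uniform", "bernoulli"}:
            raise ValueError("unknown marker distribution")


def gen_survival(spec: SurvivalSpec) -> pd.DataFrame:
    """Generate per-patient (time, event, marker) records."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + _SUB_SURV)
    kind, *params = spec.marker_distribution
    if kind == "normal":
        x = rng.normal(params[0], params[1], size=spec.n_patients)
    elif kind == "uniform":
        x = rng.uniform(params[0], params[1], size=spec.n_patients)
    else:
        x = rng.binomial(1, params[0], size=spec.n_patients).astype(float)
    rate = spec.baseline_hazard * np.exp(spec.log_hr_per_unit * x)
    t_event = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        c_rate = spec.baseline_hazard * spec.censoring_rate / (1 - spec.censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=spec.n_patients)
    else:
        t_cens = np.full(spec.n_patients, np.inf)
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    return pd.DataFrame({"time": time, "event": event, "marker": x})


@dataclass(frozen=True)
class ImageSceneSpec:
    """Two-channel fluorescence scene with disk-rendered cells and droplets."""

    height: int = 512
    width: int = 512
    n_cells: int = 8
    nucleus_radius: tuple[float, float] = (12.0, 16.0)
    cell_radius: tuple[float, float] = (38.0, 50.0)
    droplet_radius: tuple[float, float] = (2.0, 3.0)
    droplets_per_cell: tuple[int, int] = (3, 8)
    background_level: float = 0.05
    cytoplasm_level: float = 0.25
    nucleus_level: float = 0.80
    droplet_level: float = 0.90
    gaussian_noise_sd: float = 0.0
    min_separation: float = 10.0  # between droplet centers within a cell
    seed: int = 0

    def validate(self) -> None:
        if self.nucleus_radius[1] >= self.cell_radius[0]:
            raise ValueError("nucleus_radius must be smaller than cell_radius")
        for r in (self.nucleus_radius, self.cell_radius, self.droplet_radius):
            if r[0] <= 0 or r[1] < r[0]:
                raise ValueError("radii ranges must be positive and ordered")
        if self.n_cells > 0 and 2 * self.cell_radius[1] + 4 > min(self.height, self.width):
            raise ValueError("cells do not fit within the frame")
        if self.droplets_per_cell[0] < 0 or self.droplets_per_cell[1] < self.droplets_per_cell[0]:
            raise ValueError("droplets_per_cell must be a valid range")


@dataclass
class SceneTruth:
    """Ground truth of a generated scene."""

    nuclei: list  # (row, col, radius)
    cell_labels: np.ndarray
    droplets: dict  # cell label -> list of (row, col, radius)
    covered_fraction: float | None = None

    @property
    def n_droplets(self) -> int:
        return sum(len(v) for v in self.droplets.values())


def _aa_disk(shape, center, radius):
    """Anti-aliased disk coverage: 1 inside, 0 outside, 1-px ramp at the rim."""
    r0, c0 = center
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    d = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
    return np.clip(radius + 0.5 - d, 0.0, 1.0)


def _place_points(rng, n, sampler, min_dist, max_tries=500, what="object"):
    pts = []
    tries = 0
    while len(pts) < n:
        cand = sampler()
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_dist**2 for p in pts):
            pts.append(cand)
            tries = 0
        else:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"could not place {n} {what}s with min separation "
                    f"{min_dist:.1f} px after {max_tries} retries"
                )
    return pts


def gen_fluor_scene(spec: ImageSceneSpec):
    """Generate a (2, H, W) fluorescence image and its :class:`SceneTruth`."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + _SUB_SCENE)
    H, W = spec.height, spec.width
    nuc = np.full((H, W), spec.background_level)
    drop = np.full((H, W), spec.background_level)
    labels = np.zeros((H, W), dtype=np.int32)
    nuclei = []
    droplets: dict[int, list] = {}

    if spec.n_cells > 0:
        r_max = spec.cell_radius[1]
        margin = r_max + 2

        def cell_sampler():
            return (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))

        centers = _place_points(
            rng, spec.n_cells, cell_sampler, 2 * r_max + 4, what="cell"
        )
        for lab, (r0, c0) in enumerate(centers, start=1):
            cell_r = rng.uniform(*spec.cell_radius)
            nuc_r = rng.uniform(*spec.nucleus_radius)
            cell_cov = _aa_disk((H, W), (r0, c0), cell_r)
            nuc_cov = _aa_disk((H, W), (r0, c0), nuc_r)
            drop += (spec.cytoplasm_level - spec.background_level) * cell_cov
            nuc += (spec.nucleus_level - spec.background_level) * nuc_cov
            labels[cell_cov >= 0.5] = lab
            nuclei.append((r0, c0, nuc_r))

            n_d = int(rng.integers(spec.droplets_per_cell[0], spec.droplets_per_cell[1] + 1))
            d_list = []
            if n_d:
                d_r_max = spec.droplet_radius[1]
                reach = cell_r - d_r_max - 2

                def droplet_sampler():
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = reach * np.sqrt(rng.uniform())
                    return (r0 + rad * np.sin(ang), c0 + rad * np.cos(ang))

                pts = _place_points(
                    rng, n_d, droplet_sampler, spec.min_separation, what="droplet"
                )
                for (dr, dc) in pts:
                    d_rad = rng.uniform(*spec.droplet_radius)
                    cov = _aa_disk((H, W), (dr, dc), d_rad)
                    drop += (spec.droplet_level - spec.cytoplasm_level) * cov
                    d_list.append((dr, dc, d_rad))
            droplets[lab] = d_list

    if spec.gaussian_noise_sd > 0:
        nuc = nuc + rng.normal(0, spec.gaussian_noise_sd, size=(H, W))
        drop = drop + rng.normal(0, spec.gaussian_noise_sd, size=(H, W))
    image = np.clip(np.stack([nuc, drop]), 0.0, 1.0)
    return image, SceneTruth(nuclei, labels, droplets)


@dataclass(frozen=True)
class StainSpec:
    """Stained-area image: dark blobs on a light background."""

    height: int = 256
    width: int = 256
    blob_radius: tuple[float, float] = (8.0, 16.0)
    background_level: float = 0.90
    stain_level: float = 0.15
    gaussian_noise_sd: float = 0.0
    seed: int = 0


def gen_stained_image(target_fraction: float, spec: StainSpec = StainSpec()):
    """Generate a stained image whose truth records the exact covered fraction.

    Dark disks accumulate until the binary coverage mask reaches
    ``target_fraction``; the truth fraction is the realized pixel fraction
    of that mask (so it can overshoot the target by at most one blob).
    """
    if not 0 <= target_fraction <= 1:
        raise ValueError("target_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed + _SUB_STAIN)
    H, W = spec.height, spec.width
    covered = np.zeros((H, W), dtype=bool)
    coverage = np.zeros((H, W))
    if target_fraction >= 1.0:
        covered[:] = True
        coverage[:] = 1.0
    else:
        guard = 0
        while covered.mean() < target_fraction and guard < 100000:
            guard += 1
            r = rng.uniform(*spec.blob_radius)
            center = (rng.uniform(0, H), rng.uniform(0, W))
            cov = _aa_disk((H, W), center, r)
            coverage = np.maximum(coverage, cov)
            covered |= cov >= 0.5
    image = spec.background_level + (spec.stain_level - spec.background_level) * coverage
    if spec.gaussian_noise_sd > 0:
        image = image + rng.normal(0, spec.gaussian_noise_sd, size=(H, W))
    image = np.clip(image, 0.0, 1.0)
    truth = SceneTruth([], np.zeros((H, W), dtype=np.int32), {},
                       covered_fraction=float(covered.mean()))
    return image, truth


# ---------------------------------------------------------------------------
# writers for the standard pipeline inputs


def write_cohort(out_dir, counts: CountMatrix, beta: BetaMatrix,
                 annotation: pd.DataFrame, sheet: pd.DataFrame,
                 truth: CohortTruth) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tab = counts.counts.copy()
    tab.insert(0, "length", counts.lengths.reindex(tab.index))
    tab.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
    beta.values.to_csv(out / "beta.tsv", sep="\t", index_label="probe")
    annotation.to_csv(out / "annotation.tsv", sep="\t", index_label="probe")
    sheet.to_csv(out / "samples.csv", index=False)
    truth.table.to_csv(out / "truth.csv", index=False)


def write_survival(out_dir, records: pd.DataFrame) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "survival.csv", index=False)


def write_scene(out_dir, image: np.ndarray, truth: SceneTruth,
                name: str = "scene") -> None:
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arr = np.round(np.clip(image, 0, 1) * 65535).astype(np.uint16)
    tifffile.imwrite(out / f"{name}.tif", arr)
    payload = {
        "nuclei": [list(map(float, n)) for n in truth.nuclei],
        "droplets": {
            str(k): [list(map(float, d)) for d in v] for k, v in truth.droplets.items()
        },
        "covered_fraction": truth.covered_fraction,
    }
    (out / f"{name}_truth.json").write_text(json.dumps(payload, indent=1))
    tifffile.imwrite(out / f"{name}_labels.tif", truth.cell_labels.astype(np.uint16))
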