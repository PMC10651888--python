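"""Synthetic data generators with known ground truth.

Every downstream stage (differential enrichment, set algebra, feature
statistics, kinetic clustering, image quantification) is testable against the
truth objects returned here, without any external download.  All generators
are pure functions of (spec, seed): a single numpy Generator is seeded once
per call and all draws flow from it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    CountMatrix,
    GeneSetTable,
    ImageStack,
    SpecError,
    GeometryError,
)

# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------


@dataclass
class PlantedEffect:
    """A multiplicative fold change applied to samples matching `where`.

    where : metadata column -> value; a sample receives the effect iff it
        matches every entry.  In the canonical three-contrast labeling design
        a single effect on {bait: targeted, probe: PA, fraction: post} makes
        all three contrasts (post-vs-pre, +PA-vs--PA, targeted-vs-untargeted)
        see the same log2 fold change.
    log2fc : gene id -> planted log2 fold change.
    """

    where: dict[str, str]
    log2fc: dict[str, float]


@dataclass
class CountSimTruth:
    """Ground truth of a count simulation."""

    planted_effects: list[PlantedEffect]
    baseline_means: pd.Series
    dispersions: pd.Series
    size_factors: pd.Series
    seed: int

    def planted_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for eff in self.planted_effects:
            out |= {g for g, fc in eff.log2fc.items() if fc != 0}
        return frozenset(out)


def labeling_design(stress: str = "arsenite", timepoint: str = "T0",
                    n_reps: int = 2, n_reps_untargeted: int = 4
                    ) -> pd.DataFrame:
    """Sample sheet for one labeling experiment's three-contrast design.

    Mirrors the study layout: the bait-fused line contributes post-enrichment
    (+PA), pre-enrichment (+PA) and omit-probe (post) samples; the untargeted
    line contributes post-enrichment +PA controls.  Replicate counts default
    to the study's (two biological replicates per condition, four for the
    untargeted control line).
    """
    rows = []
    conds = [
        ("targeted", "PA", "post", n_reps),
        ("targeted", "PA", "pre", n_reps),
        ("targeted", "noPA", "post", n_reps),
        ("untargeted", "PA", "post", n_reps_untargeted),
    ]
    for bait, probe, fraction, reps in conds:
        for r in range(1, reps + 1):
            name = f"{bait}_{probe}_{fraction}_r{r}"
            rows.append({"sample": name, "bait": bait, "probe": probe,
                         "fraction": fraction, "stress": stress,
                         "timepoint": timepoint, "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


def two_group_design(n_a: int = 3, n_b: int = 3, stress: str = "arsenite",
                     timepoint: str = "T0") -> pd.DataFrame:
    """Minimal targeted-vs-untargeted two-group sample sheet."""
    rows = []
    for bait, n in (("targeted", n_a), ("untargeted", n_b)):
        for r in range(1, n + 1):
            rows.append({"sample": f"{bait}_r{r}", "bait": bait, "probe": "PA",
                         "fraction": "post", "stress": stress,
                         "timepoint": timepoint, "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


def simulate_counts(n_genes: int,
                    design: pd.DataFrame,
                    planted: Sequence[PlantedEffect] = (),
                    seed: int = 17,
                    mean_log_mu: float = 5.0,
                    mean_log_sigma: float = 1.0,
                    dispersion: float | Sequence[float] = 0.05,
                    size_factor_sigma: float = 0.0,
                    gene_prefix: str = "G",
                    ) -> tuple[CountMatrix, CountSimTruth]:
    """Simulate an NB count matrix with planted per-contrast fold changes.

    Counts are negative binomial with Var = m + d * m^2 (gamma-Poisson
    mixture).  Baseline means are log-normal (natural-log mu/sigma).  Planted
    effects multiply the mean of matching samples by 2**log2fc.  Size factors
    are log-normal with sd `size_factor_sigma` (0 -> all 1), renormalized to
    geometric mean 1.
    """
    if n_genes < 1:
        raise SpecError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"{gene_prefix}{i:05d}" for i in range(n_genes)]
    gene_set = set(genes)
    for eff in planted:
        unknown = set(eff.log2fc) - gene_set
        if unknown:
            raise SpecError(f"planted effect references unknown genes: "
                            f"{sorted(unknown)[:5]}")
        bad_cols = set(eff.where) - set(design.columns)
        if bad_cols:
            raise SpecError(f"planted effect predicates unknown columns: {bad_cols}")

    base = rng.lognormal(mean_log_mu, mean_log_sigma, size=n_genes)
    disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_genes,)).copy()
    if (disp <= 0).any():
        raise SpecError("dispersions must be > 0")

    n_samples = len(design)
    if size_factor_sigma > 0:
        sf = rng.lognormal(0.0, size_factor_sigma, size=n_samples)
        sf /= np.exp(np.mean(np.log(sf)))
    else:
        sf = np.ones(n_samples)

    # per-sample, per-gene multiplier from planted effects
    mult = np.ones((n_genes, n_samples))
    gene_index = {g: i for i, g in enumerate(genes)}
    for eff in planted:
        match = np.ones(n_samples, dtype=bool)
        for col, val in eff.where.items():
            match &= (design[col] == val).to_numpy()
        for g, fc in eff.log2fc.items():
            mult[gene_index[g], match] *= 2.0 ** fc

    mean = base[:, None] * mult * sf[None, :]
    # gamma-Poisson: shape 1/d, mean m  ->  NB(mean m, Var m + d m^2)
    shape = 1.0 / disp[:, None]
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=list(design.index)),
        design.copy())
    truth = CountSimTruth(
        planted_effects=list(planted),
        baseline_means=pd.Series(base, index=genes),
        dispersions=pd.Series(disp, index=genes),
        size_factors=pd.Series(sf, index=list(design.index)),
        seed=seed)
    return cm, truth


def simulate_three_contrast_counts(n_genes: int = 500,
                                   n_enriched: int = 50,
                                   n_depleted: int = 0,
                                   log2fc: float = 2.0,
                                   seed: int = 17,
                                   dispersion: float = 0.05,
                                   stress: str = "arsenite",
                                   timepoint: str = "T0",
                                   n_reps: int = 2,
                                   n_reps_untargeted: int = 4,
                                   **kwargs,
                                   ) -> tuple[CountMatrix, CountSimTruth]:
    """Counts for the full labeling design with one shared enrichment effect.

    The first `n_enriched` genes get +log2fc and the next `n_depleted` genes
    get -log2fc on the (targeted, +PA, post) group, so each of the three
    standard contrasts sees the same planted fold change.
    """
    genes = [f"G{i:05d}" for i in range(n_genes)]
    fc = {g: log2fc for g in genes[:n_enriched]}
    fc.update({g: -log2fc for g in genes[n_enriched:n_enriched + n_depleted]})
    eff = PlantedEffect(
        where={"bait": "targeted", "probe": "PA", "fraction": "post"},
        log2fc=fc)
    design = labeling_design(stress=stress, timepoint=timepoint, n_reps=n_reps,
                             n_reps_untargeted=n_reps_untargeted)
    return simulate_counts(n_genes, design, [eff], seed=seed,
                           dispersion=dispersion, **kwargs)


# ---------------------------------------------------------------------------
# Annotation simulation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSimTruth:
    """Per-gene ground truth of a simulated annotation."""

    table: pd.DataFrame  # len_utr5/len_cds/len_utr3/len_total, au_* targets
    # realized values, m6a_count, te

    def __getitem__(self, gene: str) -> pd.Series:
        return self.table.loc[gene]


_REGIONS = ("utr5", "cds", "utr3")


def _random_region_seq(rng: np.random.Generator, length: int,
                       au_target: float) -> str:
    if not 0 <= au_target <= 1:
        raise SpecError(f"AU target must be in [0,1], got {au_target}")
    is_au = rng.random(length) < au_target
    au = rng.choice(list("AU"), size=length)
    gc = rng.choice(list("GC"), size=length)
    return "".join(np.where(is_au, au, gc))


def simulate_annotation(n_genes: int,
                        out_dir: str | os.PathLike,
                        seed: int = 17,
                        utr5_mean: int = 200,
                        cds_mean: int = 1500,
                        utr3_mean: int = 1000,
                        au_targets: Mapping[str, float] | None = None,
                        m6a_density_per_kb: float = 1.0,
                        te_log2_mean: float = 0.0,
                        te_log2_sd: float = 1.0,
                        te_missing_rate: float = 0.0,
                        minus_strand_prob: float = 0.5,
                        extra_isoform_prob: float = 0.0,
                        ) -> tuple[dict[str, Path], AnnotationSimTruth]:
    """Emit a GTF + contig FASTA + m6A BED + TE TSV with known truth.

    Region lengths are Poisson around the given means (floored at 30 nt so
    every region exists).  Each gene sits on its own contig as a single
    transcript; with probability `extra_isoform_prob` a strictly shorter
    second isoform is added to exercise longest-isoform selection.  m6A sites
    are Poisson with the given per-kilobase density, placed uniformly along
    the transcript and written in transcript coordinates (BED, 0-based
    half-open, chrom = gene id).
    """
    if au_targets is None:
        au_targets = {"utr5": 0.4, "cds": 0.45, "utr3": 0.6}
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    gtf_lines: list[str] = []
    fasta_lines: list[str] = []
    bed_lines: list[str] = []
    te_lines: list[str] = ["gene_id\tte"]
    records = []

    for i in range(n_genes):
        gid = f"G{i:05d}"
        tid = f"{gid}.t1"
        lens = {
            "utr5": max(30, int(rng.poisson(utr5_mean))),
            "cds": max(30, int(rng.poisson(cds_mean))),
            "utr3": max(30, int(rng.poisson(utr3_mean))),
        }
        seqs = {r: _random_region_seq(rng, lens[r], au_targets[r])
                for r in _REGIONS}
        tx_seq = seqs["utr5"] + seqs["cds"] + seqs["utr3"]
        total = len(tx_seq)
        strand = "-" if rng.random() < minus_strand_prob else "+"

        # genomic layout: single exon covering the transcript on its contig
        contig = gid
        exon = (1, total)
        if strand == "+":
            cds_start = lens["utr5"] + 1
            cds_end = lens["utr5"] + lens["cds"]
            genome_seq = tx_seq.replace("U", "T")
        else:
            # transcript runs right-to-left on the contig
            cds_start = lens["utr3"] + 1
            cds_end = lens["utr3"] + lens["cds"]
            comp = str.maketrans("ACGU", "TGCA")
            genome_seq = tx_seq.translate(comp)[::-1]

        def _gtf(feature: str, start: int, end: int, t: str) -> str:
            return ("\t".join([
                contig, "sim", feature, str(start), str(end), ".", strand, ".",
                f'gene_id "{gid}"; transcript_id "{t}";']))

        gtf_lines.append(_gtf("exon", *exon, tid))
        gtf_lines.append(_gtf("CDS", cds_start, cds_end, tid))

        if rng.random() < extra_isoform_prob and total > 120:
            # shorter isoform: drop part of the 3' end (genomically the
            # low-coordinate end for minus-strand transcripts)
            tid2 = f"{gid}.t2"
            cut = int(total * 0.6)
            if strand == "+":
                gtf_lines.append(_gtf("exon", 1, cut, tid2))
                gtf_lines.append(_gtf("CDS", cds_start, min(cds_end, cut), tid2))
            else:
                gtf_lines.append(_gtf("exon", total - cut + 1, total, tid2))
                gtf_lines.append(_gtf("CDS", max(cds_start, total - cut + 1),
                                      cds_end, tid2))

        fasta_lines.append(f">{contig}")
        for j in range(0, len(genome_seq), 70):
            fasta_lines.append(genome_seq[j:j + 70])

        n_sites = int(rng.poisson(m6a_density_per_kb * total / 1000.0))
        positions = sorted(rng.choice(total, size=min(n_sites, total),
                                      replace=False)) if n_sites else []
        for p in positions:
            bed_lines.append(f"{gid}\t{p}\t{p + 1}\tm6a")

        te_missing = rng.random() < te_missing_rate
        te_val = float(rng.normal(te_log2_mean, te_log2_sd))
        te_lines.append(f"{gid}\t{'NA' if te_missing else f'{te_val:.4f}'}")

        def _au(s: str) -> float:
            return (s.count("A") + s.count("U")) / len(s)

        records.append({
            "gene_id": gid, "transcript_id": tid, "strand": strand,
            "len_utr5": lens["utr5"], "len_cds": lens["cds"],
            "len_utr3": lens["utr3"], "len_total": total,
            "au_utr5": _au(seqs["utr5"]), "au_cds": _au(seqs["cds"]),
            "au_utr3": _au(seqs["utr3"]), "au_total": _au(tx_seq),
            "m6a_count": len(positions),
            "te": np.nan if te_missing else te_val,
        })

    paths = {
        "gtf": out_dir / "annotation.gtf",
        "fasta": out_dir / "genome.fa",
        "m6a": out_dir / "m6a_sites.bed",
        "te": out_dir / "te.tsv",
    }
    paths["gtf"].write_text("\n".join(gtf_lines) + "\n")
    paths["fasta"].write_text("\n".join(fasta_lines) + "\n")
    paths["m6a"].write_text("\n".join(bed_lines) + "\n" if bed_lines else "")
    paths["te"].write_text("\n".join(te_lines) + "\n")

    truth = AnnotationSimTruth(pd.DataFrame(records).set_index("gene_id"))
    return paths, truth


# ---------------------------------------------------------------------------
# Image simulation
# ---------------------------------------------------------------------------


@dataclass
class ImageSimTruth:
    """Ground truth of a simulated two-channel smFISH cell image."""

    granule_mask: np.ndarray
    cell_mask: np.ndarray
    puncta_centers: list[tuple[int, int]]
    inside_flags: list[bool]
    inside_fraction: float
    planted_density_ratio: float
    seed: int


def _disk_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def simulate_cell_image(shape: tuple[int, int] = (200, 200),
                        n_granules: int = 4,
                        n_puncta: int = 50,
                        inside_fraction: float = 0.7,
                        seed: int = 17,
                        n_z: int = 5,
                        granule_radius: float = 12.0,
                        punctum_radius: float = 2.0,
                        background: float = 50.0,
                        granule_amplitude: float = 150.0,
                        punctum_amplitude: float = 400.0,
                        noise_gaussian_sd: float = 0.0,
                        poisson_noise: bool = False,
                        ) -> tuple[dict[str, ImageStack], ImageSimTruth]:
    """Render a two-channel cell: granule marker channel + FISH channel.

    The cell is an ellipse filling most of the frame; granules are disks
    inside it; puncta are small bright disks placed inside the granule mask
    with probability `inside_fraction`, else uniformly in cell-minus-granule.
    Puncta centers are kept >= 2*(punctum_radius+1) apart so noise-free
    detection resolves each punctum as its own connected component.  With
    noise off, the FISH-channel punctum amplitude is far above twice the mean
    cell intensity, so threshold detection is exact.
    """
    if not 0 <= inside_fraction <= 1:
        raise SpecError("inside_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    rr, cc = np.ogrid[:ny, :nx]
    cell_mask = ((rr - cy) / (0.45 * ny)) ** 2 + ((cc - cx) / (0.45 * nx)) ** 2 <= 1.0

    granule_mask = np.zeros(shape, dtype=bool)
    placed = 0
    attempts = 0
    while placed < n_granules and attempts < 1000:
        attempts += 1
        gy = rng.uniform(granule_radius, ny - granule_radius)
        gx = rng.uniform(granule_radius, nx - granule_radius)
        disk = _disk_mask(shape, (gy, gx), granule_radius)
        if not (disk & ~cell_mask).any():
            granule_mask |= disk
            placed += 1
    if placed < n_granules:
        raise GeometryError("could not place all granules inside the cell")

    # erode the cell mask so every punctum disk fits entirely inside it
    from scipy import ndimage
    r_int = int(np.ceil(punctum_radius)) + 1
    yy, xx = np.ogrid[-r_int:r_int + 1, -r_int:r_int + 1]
    selem = yy ** 2 + xx ** 2 <= r_int ** 2
    interior = ndimage.binary_erosion(cell_mask, structure=selem)
    inside_pool = np.argwhere(interior & granule_mask)
    outside_pool = np.argwhere(interior & ~granule_mask)

    min_sep = 2 * (punctum_radius + 1)
    centers: list[tuple[int, int]] = []
    inside_flags: list[bool] = []
    attempts = 0
    while len(centers) < n_puncta:
        attempts += 1
        if attempts > 200 * n_puncta + 1000:
            raise GeometryError("could not place all puncta with the required "
                                "separation; reduce n_puncta")
        want_inside = rng.random() < inside_fraction
        pool = inside_pool if want_inside else outside_pool
        if len(pool) == 0:
            raise GeometryError("no placeable area for requested puncta")
        y, x = pool[rng.integers(len(pool))]
        if any((y - py) ** 2 + (x - px) ** 2 < min_sep ** 2 for py, px in centers):
            continue
        centers.append((int(y), int(x)))
        inside_flags.append(bool(granule_mask[y, x]))

    granule_img = np.where(cell_mask, background, 0.0)
    granule_img += np.where(granule_mask, granule_amplitude, 0.0)
    fish_img = np.where(cell_mask, background, 0.0)
    for (y, x) in centers:
        fish_img += np.where(_disk_mask(shape, (y, x), punctum_radius),
                             punctum_amplitude, 0.0)

    def _stack(img2d: np.ndarray, name: str) -> ImageStack:
        stack = np.zeros((n_z,) + shape)
        mid = n_z // 2
        for z in range(n_z):
            # signal concentrated at the focal plane, dimmer off-focus
            fade = 1.0 if z == mid else 0.3
            stack[z] = img2d * fade
        if poisson_noise:
            stack = rng.poisson(stack).astype(float)
        if noise_gaussian_sd > 0:
            stack = stack + rng.normal(0, noise_gaussian_sd, stack.shape)
        return ImageStack(name, np.clip(stack, 0, None))

    stacks = {"granule": _stack(granule_img, "granule"),
              "fish": _stack(fish_img, "fish")}

    n_in = sum(inside_flags)
    a_sg = int(granule_mask.sum())
    a_cell = int(cell_mask.sum())
    dens_in = n_in / a_sg if a_sg else 0.0
    dens_out = (n_puncta - n_in) / (a_cell - a_sg) if a_cell > a_sg else 0.0
    truth = ImageSimTruth(
        granule_mask=granule_mask, cell_mask=cell_mask,
        puncta_centers=centers, inside_flags=inside_flags,
        inside_fraction=n_in / n_puncta if n_puncta else float("nan"),
        planted_density_ratio=dens_in / dens_out if dens_out else float("inf"),
        seed=seed)
    return stacks, truth


def write_cell_image(stacks: Mapping[str, ImageStack], truth: ImageSimTruth,
                     out_dir: str | os.PathLike,
                     prefix: str = "cell") -> dict[str, Path]:
    """Write the simulated cell as a (c, z, y, x) TIFF plus an ROI polygon."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arr = np.stack([stacks["granule"].voxels, stacks["fish"].voxels])
    tiff_path = out_dir / f"{prefix}.tif"
    tifffile.imwrite(str(tiff_path), arr.astype(np.float32),
                     photometric="minisblack")

    # cell boundary polygon: ellipse slightly outside the rendered cell mask
    ny, nx = truth.cell_mask.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ry, rx = 0.45 * ny + 1.5, 0.45 * nx + 1.5
    theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
    coords = [(cx + rx * np.cos(t), cy + ry * np.sin(t)) for t in theta]
    roi_path = out_dir / f"{prefix}_roi.txt"
    roi_path.write_text("\n".join(f"{x:.2f},{y:.2f}" for x, y in coords) + "\n")
    return {"tiff": tiff_path, "roi": roi_path}


# ---------------------------------------------------------------------------
# Disassembly time-course simulation
# ---------------------------------------------------------------------------


def simulate_timecourse_counts(archetypes: Sequence[Sequence[float]] = (
                                   (2.5, 0.4, 0.2),
                                   (2.0, 1.8, 0.3),
                                   (0.3, 1.8, 2.0),
                                   (0.3, 0.4, 2.2)),
                               genes_per_cluster: int = 50,
                               noise_sd: float = 0.1,
                               seed: int = 17,
                               ) -> tuple[dict[str, pd.DataFrame],
                                          dict[str, GeneSetTable],
                                          pd.Series]:
    """Per-gene log2FC trajectories over (T0, T1, T3) around cluster archetypes.

    The default archetypes emulate the four kinetic classes seen during SG
    disassembly — rapid dissociation after stress removal, slow dissociation,
    early re-enrichment, and late re-enrichment.  Because downstream
    clustering z-scores each trajectory (it groups shapes, not magnitudes),
    the defaults are chosen to remain distinct after row scaling.

    Returns (tables, membership, labels): one contrast-style table per
    timepoint (gene_id, log2fc, padj), per-timepoint membership gene sets
    (all simulated genes), and the true cluster label per gene (1-based,
    in archetype order).
    """
    archetypes = [tuple(map(float, a)) for a in archetypes]
    if len(archetypes) < 2:
        raise SpecError("need at least 2 archetypes")
    if len(set(archetypes)) < len(archetypes):
        raise SpecError("archetypes must be distinct")
    if any(len(a) != 3 for a in archetypes):
        raise SpecError("archetypes must be (T0, T1, T3) triples")
    if noise_sd < 0:
        raise SpecError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    genes, labels, rowvals = [], [], []
    for k, arch in enumerate(archetypes, start=1):
        for j in range(genes_per_cluster):
            genes.append(f"C{k}_{j:04d}")
            labels.append(k)
            rowvals.append(np.asarray(arch) + rng.normal(0, noise_sd, 3))
    mat = np.asarray(rowvals)

    timepoints = ("T0", "T1", "T3")
    tables = {}
    for t_i, tp in enumerate(timepoints):
        tables[tp] = pd.DataFrame({
            "gene_id": genes,
            "log2fc": mat[:, t_i],
            "padj": 1e-6,
        }).set_index("gene_id")
    membership = {tp: GeneSetTable(tp, frozenset(genes)) for tp in timepoints}
    return tables, membership, pd.Series(labels, index=genes, name="cluster")


# ---------------------------------------------------------------------------
# Published-overlap gene lists (synthetic stand-ins)
# ---------------------------------------------------------------------------


@dataclass
class StudyOverlapDesign:
    """Block sizes of the study's five G3BP1-proximal lists.

    The blocks are disjoint; each list is a union of blocks.  Defaults encode
    the published overlap geometry of the HEK293T arsenite (457), HEK293T
    sorbitol (822), HEK293T basal (731), HEK293T T3-recovery (428) and U-2 OS
    arsenite (1135) SG/G3BP1-proximal transcript lists.
    """

    ars_sorb_basal: int = 51        # in arsenite, sorbitol and basal
    ars_sorb_only: int = 92         # in both stresses, not basal
    ars_basal_only: int = 80        # arsenite & basal, not sorbitol
    sorb_basal_only: int = 122      # sorbitol & basal, not arsenite
    ars_only: int = 234             # arsenite only
    sorb_only: int = 557            # sorbitol only
    basal_specific: int = 478       # basal only (w.r.t. the two stresses)
    t3_shared_basal: int = 126      # T3 & basal
    t3_only: int = 302              # T3 only
    u2os_shared_ars: int = 261      # U-2 OS & HEK arsenite
    u2os_only: int = 874            # U-2 OS only

    def sizes(self) -> dict[str, int]:
        d = self
        return {
            "arsenite": d.ars_sorb_basal + d.ars_sorb_only + d.ars_basal_only
                        + d.ars_only,
            "sorbitol": d.ars_sorb_basal + d.ars_sorb_only + d.sorb_basal_only
                        + d.sorb_only,
            "basal": d.ars_sorb_basal + d.ars_basal_only + d.sorb_basal_only
                     + d.basal_specific,
            "t3": d.t3_shared_basal + d.t3_only,
            "u2os": d.u2os_shared_ars + d.u2os_only,
        }


def simulate_study_gene_lists(seed: int = 17,
                              design: StudyOverlapDesign | None = None
                              ) -> dict[str, GeneSetTable]:
    """Generate synthetic gene-id lists realizing a declared overlap design.

    The identifiers are synthetic (SYNG-prefixed), but the overlap block
    structure — which genes are shared between which condition lists — follows
    `design` exactly, so set-level statistics computed downstream are fully
    determined.  The basal members shared with T3 and the arsenite members
    shared with U-2 OS are drawn (seeded) uniformly from their parent lists;
    the published geometry does not constrain those cross sections further.
    """
    if design is None:
        design = StudyOverlapDesign()
    rng = np.random.default_rng(seed)

    counter = [0]

    def fresh(n: int) -> list[str]:
        ids = [f"SYNG{counter[0] + i:05d}" for i in range(n)]
        counter[0] += n
        return ids

    b_asb = fresh(design.ars_sorb_basal)
    b_as = fresh(design.ars_sorb_only)
    b_ab = fresh(design.ars_basal_only)
    b_sb = fresh(design.sorb_basal_only)
    b_a = fresh(design.ars_only)
    b_s = fresh(design.sorb_only)
    b_b = fresh(design.basal_specific)

    arsenite = b_asb + b_as + b_ab + b_a
    sorbitol = b_asb + b_as + b_sb + b_s
    basal = b_asb + b_ab + b_sb + b_b

    if design.t3_shared_basal > len(basal):
        raise SpecError("t3_shared_basal exceeds basal list size")
    t3_from_basal = list(rng.choice(basal, size=design.t3_shared_basal,
                                    replace=False))
    t3 = t3_from_basal + fresh(design.t3_only)

    if design.u2os_shared_ars > len(arsenite):
        raise SpecError("u2os_shared_ars exceeds arsenite list size")
    u2os_from_ars = list(rng.choice(arsenite, size=design.u2os_shared_ars,
                                    replace=False))
    u2os = u2os_from_ars + fresh(design.u2os_only)

    return {name: GeneSetTable(name, frozenset(ids))
            for name, ids in (("arsenite", arsenite), ("sorbitol", sorbitol),
                              ("basal", basal), ("t3", t3), ("u2os", u2os))}
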