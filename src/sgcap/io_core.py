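"""Readers, writers, domain containers and run configuration.

The pipeline's entry point is a gene-level count matrix (htseq-count style
TSV) plus a factorial sample sheet describing the proximity-labeling design:
bait (G3BP1-fused vs untargeted photocatalyst), probe (+PA vs -PA), fraction
(pre vs post streptavidin enrichment), stress, recovery timepoint and
replicate.  Everything downstream (differential enrichment, set algebra,
feature statistics, imaging) consumes the containers defined here.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import io
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Point, Polygon

logger = logging.getLogger("sgcap")

__version__ = "0.1.0"

BAIT_LEVELS = ("targeted", "untargeted")
PROBE_LEVELS = ("PA", "noPA")
FRACTION_LEVELS = ("pre", "post")
STRESS_LEVELS = ("none", "arsenite", "sorbitol")
TIMEPOINT_LEVELS = ("T0", "T1", "T3")

METADATA_LEVELS = {
    "bait": BAIT_LEVELS,
    "probe": PROBE_LEVELS,
    "fraction": FRACTION_LEVELS,
    "stress": STRESS_LEVELS,
    "timepoint": TIMEPOINT_LEVELS,
}


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class SgcapError(Exception):
    """Base class for all package errors."""


class FormatError(SgcapError):
    """Malformed input file (wrong dtype, negative count, bad field)."""


class MetadataError(SgcapError):
    """Sample metadata missing or inconsistent with the count matrix."""


class EmptyInputError(SgcapError):
    """An input that must be non-empty is empty."""


class AnnotationError(SgcapError):
    """Malformed transcript annotation (e.g. CDS outside exons)."""


class GeometryError(SgcapError):
    """Image/ROI geometry problem (open polygon, off-grid ROI...)."""


class ChannelMismatchError(SgcapError):
    """Image stack does not carry the expected number of channels."""


class ConfigError(SgcapError):
    """Invalid run configuration value or unknown key."""


class DesignError(SgcapError):
    """Invalid contrast or experimental-design request."""


class NormalizationError(SgcapError):
    """Size-factor estimation impossible (no gene nonzero everywhere)."""


class UniverseError(SgcapError):
    """Gene-set members fall outside the declared universe."""


class SpecError(SgcapError):
    """Invalid simulation specification."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Thresholds and parameters shared across pipeline stages.

    fc_threshold : log2 fold-change cutoff (strict inequality) used for both
        the enriched (> fc_threshold) and depleted (< -fc_threshold) calls.
    alpha : BH-adjusted p-value cutoff (strict inequality).
    fold_threshold : smFISH puncta intensity rule — candidate pixels must be
        at least fold_threshold times the mean cell intensity.
    min_area_px : minimum puncta component area in pixels.
    k : number of kinetic clusters for the disassembly time course.
    seed : base seed for every stochastic operation.
    """

    fc_threshold: float = 0.3
    alpha: float = 0.05
    fold_threshold: float = 2.0
    min_area_px: int = 12
    k: int = 4
    seed: int = 17

    def __post_init__(self) -> None:
        if not self.fc_threshold > 0:
            raise ConfigError(f"fc_threshold must be > 0, got {self.fc_threshold}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.fold_threshold > 0:
            raise ConfigError(f"fold_threshold must be > 0, got {self.fold_threshold}")
        if self.min_area_px < 1:
            raise ConfigError(f"min_area_px must be >= 1, got {self.min_area_px}")
        if self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        """Load a YAML key-value config, rejecting unknown keys with a hint."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a key-value mapping")
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                hint = difflib.get_close_matches(str(key), known, n=1)
                suffix = f" (did you mean '{hint[0]}'?)" if hint else ""
                raise ConfigError(f"unknown config key '{key}'{suffix}")
        return cls(**{k: v for k, v in raw.items()})  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logging."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def setup_logging(logfile: str | None = None, level: int = logging.INFO) -> None:
    """Console (and optionally file) logging for CLI runs."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample counts plus factorial metadata.

    counts : DataFrame indexed by gene id, one column per sample.
    samples : DataFrame indexed by sample name with columns
        bait/probe/fraction/stress/timepoint/replicate, in count-column order.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                bad = self._first_bad(lambda v: not np.isfinite(v) or v != np.floor(v))
                raise FormatError(f"non-integer count at gene={bad[0]} sample={bad[1]}")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = self._first_bad(lambda v: v < 0)
            raise FormatError(f"negative count at gene={bad[0]} sample={bad[1]}")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise MetadataError(f"samples missing from metadata: {missing}")
        required = ["bait", "probe", "fraction", "stress", "timepoint", "replicate"]
        absent = [c for c in required if c not in self.samples.columns]
        if absent:
            raise MetadataError(f"metadata lacks required columns: {absent}")
        for col, levels in METADATA_LEVELS.items():
            bad_vals = set(self.samples[col]) - set(levels)
            if bad_vals:
                raise MetadataError(f"invalid {col} values: {sorted(bad_vals)}")
        if (self.samples["replicate"].astype(int) < 1).any():
            raise MetadataError("replicate numbers must be positive integers")
        # keep metadata in count-column order
        self.samples = self.samples.loc[list(self.counts.columns)]

    def _first_bad(self, pred) -> tuple[str, str]:
        for g, row in self.counts.iterrows():
            for s, v in row.items():
                if pred(v):
                    return str(g), str(s)
        raise AssertionError("no offending cell found")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, mask: pd.Series | Sequence[bool]) -> "CountMatrix":
        keep = self.samples.index[np.asarray(mask, dtype=bool)]
        return CountMatrix(self.counts[list(keep)], self.samples.loc[keep])


def read_count_matrix(path: str | os.PathLike,
                      metadata_path: str | os.PathLike) -> CountMatrix:
    """Read a gene x sample count TSV and its sample sheet.

    The count file's first column holds gene ids; remaining columns are
    samples. The sample sheet is keyed by sample name and must cover every
    count column.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if counts.empty:
        raise EmptyInputError(f"count matrix {path} has no rows")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, comment="#")
    return CountMatrix(counts, meta)


def write_table(df: pd.DataFrame, path: str | os.PathLike,
                config: RunConfig | None = None,
                index: bool = True) -> None:
    """Write a TSV with a comment header recording version, config and seed."""
    with open(path, "w") as fh:
        fh.write(f"# sgcap {__version__}\n")
        if config is not None:
            fh.write(f"# config {config.digest()} seed {config.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetTable:
    """A named set of gene identifiers, optionally bounded by a universe."""

    name: str
    members: frozenset[str]
    universe_hint: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if self.universe_hint is not None:
            self.universe_hint = frozenset(self.universe_hint)
            stray = self.members - self.universe_hint
            if stray:
                raise UniverseError(
                    f"set '{self.name}' has members outside its universe: "
                    f"{sorted(stray)[:5]}")

    def __len__(self) -> int:
        return len(self.members)


def read_gene_sets(path: str | os.PathLike) -> dict[str, GeneSetTable]:
    """Read gene lists: one id per line, or a two-column id<TAB>category TSV.

    Returns one GeneSetTable per category ("set" for the single-column form).
    Duplicate ids within a category are collapsed with a logged warning.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts and parts[0].lower() in ("gene_id", "gene", "id"):
                continue  # header
            if len(parts) == 1:
                rows.append((parts[0], "set"))
            else:
                rows.append((parts[0], parts[1]))
    if not rows:
        raise EmptyInputError(f"gene-set file {path} is empty")
    out: dict[str, GeneSetTable] = {}
    by_cat: dict[str, list[str]] = {}
    for gid, cat in rows:
        by_cat.setdefault(cat, []).append(gid)
    for cat, ids in by_cat.items():
        uniq = frozenset(ids)
        if len(uniq) < len(ids):
            logger.warning("gene set '%s': %d duplicate ids collapsed",
                           cat, len(ids) - len(uniq))
        out[cat] = GeneSetTable(cat, uniq)
    return out


def write_gene_set(gs: GeneSetTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gid in sorted(gs.members):
            fh.write(f"{gid}\n")


# ---------------------------------------------------------------------------
# Transcript annotation
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """One transcript's exon/CDS structure and spliced region sequences.

    Coordinates follow GTF convention (1-based inclusive, genomic).
    Sequences are spliced, 5'->3' in transcript orientation, RNA alphabet
    (T mapped to U on input).
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    seq_full: str = ""
    seq_utr5: str = ""
    seq_cds: str = ""
    seq_utr3: str = ""

    @property
    def len_utr5(self) -> int:
        return len(self.seq_utr5)

    @property
    def len_cds(self) -> int:
        return len(self.seq_cds)

    @property
    def len_utr3(self) -> int:
        return len(self.seq_utr3)

    @property
    def len_total(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def spliced_seq(self) -> str:
        return self.seq_full


_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def load_annotation(gtf_path: str | os.PathLike,
                    fasta_path: str | os.PathLike,
                    fasta_keyed_by: str = "genome") -> dict[str, TranscriptModel]:
    """Parse a GTF plus sequences into per-transcript models.

    fasta_keyed_by : "genome" (FASTA records are chromosomes/contigs; spliced
        sequences are extracted strand-aware) or "transcript" (records are
        already-spliced transcript sequences, 5'->3').

    The transcript is decomposed into 5'UTR / CDS / 3'UTR by transcript
    coordinates of the CDS span.  Transcripts without CDS records (non-coding)
    keep all three region sequences empty; the full spliced sequence remains
    available via `seq_full` for total-length/AU statistics.
    """
    import gffutils
    from Bio import SeqIO

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True)

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}

    models: dict[str, TranscriptModel] = {}
    feature_types = set(db.featuretypes())
    exon_parent: dict[str, dict] = {}
    for ftype in ("exon", "CDS"):
        if ftype not in feature_types:
            continue
        for feat in db.features_of_type(ftype):
            tid = feat.attributes.get("transcript_id", [None])[0]
            gid = feat.attributes.get("gene_id", [tid])[0]
            if tid is None:
                raise AnnotationError(f"{ftype} record lacks transcript_id")
            entry = exon_parent.setdefault(
                tid, {"gene_id": gid, "strand": feat.strand,
                      "chrom": feat.seqid, "exons": [], "cds": []})
            key = "exons" if ftype == "exon" else "cds"
            entry[key].append((feat.start, feat.end))

    for tid, entry in exon_parent.items():
        exons = sorted(entry["exons"])
        cds = sorted(entry["cds"])
        strand = entry["strand"]
        if strand not in ("+", "-"):
            raise AnnotationError(f"transcript {tid}: strand must be + or -")
        if not exons:
            raise AnnotationError(f"transcript {tid} has CDS but no exons")
        for cs, ce in cds:
            if not any(es <= cs and ce <= ee for es, ee in exons):
                raise AnnotationError(
                    f"transcript {tid}: CDS {cs}-{ce} not contained in exons")

        # genomic -> transcript coordinate map (transcript 5'->3')
        blocks = exons if strand == "+" else exons[::-1]

        def tx_pos(gpos: int) -> int:
            off = 0
            for es, ee in blocks:
                if es <= gpos <= ee:
                    return off + (gpos - es if strand == "+" else ee - gpos)
                off += ee - es + 1
            raise AnnotationError(f"transcript {tid}: position {gpos} not exonic")

        if fasta_keyed_by == "transcript":
            if tid not in seqs:
                logger.warning("transcript %s absent from FASTA; skipped", tid)
                continue
            spliced = _to_rna(seqs[tid])
        else:
            chrom = entry["chrom"]
            if chrom not in seqs:
                logger.warning("contig %s absent from FASTA; transcript %s skipped",
                               chrom, tid)
                continue
            contig = seqs[chrom]
            parts = [contig[s - 1:e] for s, e in exons]
            spliced = _to_rna("".join(parts))
            if strand == "-":
                spliced = _revcomp_rna(spliced)
        total_len = sum(e - s + 1 for s, e in exons)
        if len(spliced) != total_len:
            raise AnnotationError(
                f"transcript {tid}: sequence length {len(spliced)} != exon "
                f"length {total_len}")

        if cds:
            cds_ends = [tx_pos(cs) for cs, ce in cds] + [tx_pos(ce) for cs, ce in cds]
            c0, c1 = min(cds_ends), max(cds_ends)
            utr5, cds_seq, utr3 = spliced[:c0], spliced[c0:c1 + 1], spliced[c1 + 1:]
        else:
            utr5, cds_seq, utr3 = "", "", ""
        models[tid] = TranscriptModel(
            gene_id=entry["gene_id"], transcript_id=tid, strand=strand,
            exons=exons, cds=cds, seq_full=spliced,
            seq_utr5=utr5, seq_cds=cds_seq, seq_utr3=utr3)
    return models


# ---------------------------------------------------------------------------
# Feature resources: m6A site table, translation efficiency
# ---------------------------------------------------------------------------

def load_feature_resources(m6a_path: str | os.PathLike | None,
                           te_path: str | os.PathLike | None
                           ) -> tuple[dict[str, list[int]], dict[str, float]]:
    """Load the m6A site table (BED-like, 0-based half-open) and the TE table.

    Returns (sites, te): sites maps gene/transcript id -> sorted positions;
    te maps gene id -> log2(RPF/RNA).  Genes absent from either resource are
    simply absent from the mapping (missing, not zero).  TE values of "NA" or
    empty are treated as missing.
    """
    sites: dict[str, list[int]] = {}
    if m6a_path is not None:
        with open(m6a_path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{m6a_path}:{ln}: BED needs >= 3 columns")
                gid, start = parts[0], parts[1]
                try:
                    pos = int(start)
                except ValueError as exc:
                    raise FormatError(f"{m6a_path}:{ln}: bad position '{start}'") from exc
                sites.setdefault(gid, []).append(pos)
        for gid in sites:
            sites[gid].sort()

    te: dict[str, float] = {}
    if te_path is not None:
        with open(te_path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].lower() in ("gene_id", "gene", "id"):
                    continue
                if len(parts) < 2:
                    raise FormatError(f"{te_path}:{ln}: TE rows need gene<TAB>value")
                gid, val = parts[0], parts[1]
                if val == "" or val.upper() in ("NA", "NAN"):
                    continue  # missing, not an error
                try:
                    te[gid] = float(val)
                except ValueError as exc:
                    raise FormatError(f"{te_path}:{ln}: unparsable TE '{val}'") from exc
    return sites, te


# ---------------------------------------------------------------------------
# Images and ROIs
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """One channel's voxel data (z, y, x) with physical calibration."""

    channel: str
    voxels: np.ndarray
    pixel_size_um: float = 0.1
    z_step_um: float = 0.4

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"stack must be (z, y, x); got shape {self.voxels.shape}")
        if (self.voxels < 0).any():
            raise FormatError("negative intensities in image stack")


def read_roi(path: str | os.PathLike) -> list[tuple[float, float]]:
    """Read a polygon ROI as 'x,y' lines (0-based pixel-center coordinates)."""
    pts: list[tuple[float, float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                x, y = line.split(",")
                pts.append((float(x), float(y)))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: expected 'x,y'") from exc
    if len(pts) < 3:
        raise GeometryError(f"ROI polygon needs >= 3 vertices, got {len(pts)}")
    return pts


def rasterize_roi(vertices: Sequence[tuple[float, float]],
                  shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon to a boolean mask.

    A pixel (row, col) is inside iff the polygon covers the point
    (x=col, y=row); boundary points count as inside.
    """
    poly = Polygon(vertices)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty:
        raise GeometryError("ROI polygon is degenerate")
    ny, nx = shape
    minx, miny, maxx, maxy = poly.bounds
    if maxx < 0 or maxy < 0 or minx > nx - 1 or miny > ny - 1:
        raise GeometryError("ROI polygon lies entirely outside the image")
    mask = np.zeros(shape, dtype=bool)
    c0 = max(0, int(np.floor(minx)))
    c1 = min(nx - 1, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny)))
    r1 = min(ny - 1, int(np.ceil(maxy)))
    from shapely import covers, points
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    pts = points(cols.ravel().astype(float), rows.ravel().astype(float))
    inside = covers(poly, pts).reshape(rows.shape)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    return mask


def load_image_inputs(tiff_path: str | os.PathLike,
                      roi_path: str | os.PathLike,
                      n_channels: int = 2,
                      channel_names: Sequence[str] = ("granule", "fish"),
                      channel_axis: int = 0,
                      pixel_size_um: float = 0.1,
                      z_step_um: float = 0.4
                      ) -> tuple[dict[str, ImageStack], np.ndarray]:
    """Load a multi-channel TIFF stack and a cell-boundary ROI.

    The TIFF is expected as (channel, z, y, x) (or (z, y, x) for a single
    channel).  Returns ({channel_name: ImageStack}, cell_mask).
    """
    arr = tifffile.imread(str(tiff_path))
    if arr.ndim == 3 and n_channels == 1:
        arr = arr[None]
    if arr.ndim != 4:
        raise FormatError(f"expected (c, z, y, x) TIFF; got shape {arr.shape}")
    if channel_axis != 0:
        arr = np.moveaxis(arr, channel_axis, 0)
    if arr.shape[0] != n_channels:
        raise ChannelMismatchError(
            f"expected {n_channels} channels, found {arr.shape[0]}")
    stacks = {
        name: ImageStack(name, arr[i].astype(float),
                         pixel_size_um=pixel_size_um, z_step_um=z_step_um)
        for i, name in enumerate(channel_names)
    }
    vertices = read_roi(roi_path)
    mask = rasterize_roi(vertices, arr.shape[-2:])
    return stacks, mask
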