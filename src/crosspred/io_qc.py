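"""Genotype, map, phenotype and cross-list I/O plus marker quality control.

Genotype calls count copies of the alphabetically-first nucleotide allele at
each SNP, so every call is 0, 1 or 2 (heterozygote = 1).  Missing calls are
held internally as the sentinel :data:`MISSING` (-1) and written out as
``NA``.  The QC step mirrors a standard chip-genotyping pipeline: markers are
dropped when their minor-allele frequency falls below a threshold or when too
many lines lack a call, and the residual missing calls are filled with a
simple single-marker imputer (a stand-in for haplotype-based imputation,
which is out of scope here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

_MISSING_TOKENS = {"NA", "", ".", "NAN", "nan", "NaN"}


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class GenotypeMatrix:
    """Lines x markers grid of allele counts in {0, 1, 2} with missing = -1."""

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = [str(i) for i in self.line_ids]
        self.marker_ids = [str(i) for i in self.marker_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        _check_unique(self.line_ids, "line")
        _check_unique(self.marker_ids, "marker")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid call {self.calls[r, c]} at line {self.line_ids[r]!r}, "
                f"marker {self.marker_ids[c]!r}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def has_missing(self) -> bool:
        return bool((self.calls == MISSING).any())

    def line_index(self, line_id: str) -> int:
        try:
            return self.line_ids.index(str(line_id))
        except ValueError:
            raise KeyError(f"unknown line id: {line_id!r}") from None

    def row(self, line_id: str) -> np.ndarray:
        return self.calls[self.line_index(line_id)]

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.line_ids),
            [self.marker_ids[i] for i in idx],
            self.calls[:, idx].copy(),
        )

    def subset_lines(self, line_ids) -> "GenotypeMatrix":
        idx = [self.line_index(i) for i in line_ids]
        return GenotypeMatrix(
            [self.line_ids[i] for i in idx], list(self.marker_ids), self.calls[idx].copy()
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.calls, index=self.line_ids, columns=self.marker_ids)
        return df.astype(object).where(df.values != MISSING, other="NA")


@dataclass
class GeneticMap:
    """Ordered marker positions (cM) on named chromosomes.

    Storage order is the canonical marker order: chromosomes appear as
    contiguous blocks and positions are non-decreasing within a chromosome.
    """

    frame: pd.DataFrame  # columns marker_id, chromosome, position_cM

    def __post_init__(self) -> None:
        f = self.frame
        required = {"marker_id", "chromosome", "position_cM"}
        if not required.issubset(f.columns):
            raise ValidationError(f"map needs columns {sorted(required)}")
        f = f.reset_index(drop=True).copy()
        f["marker_id"] = f["marker_id"].astype(str)
        f["chromosome"] = f["chromosome"].astype(str)
        f["position_cM"] = f["position_cM"].astype(float)
        _check_unique(f["marker_id"], "marker")
        if (f["position_cM"] < 0).any():
            raise ValidationError("negative cM position in genetic map")
        seen_chrom: set[str] = set()
        for chrom, grp in f.groupby("chromosome", sort=False):
            if chrom in seen_chrom:
                raise ValidationError(f"chromosome {chrom!r} is not contiguous")
            seen_chrom.add(chrom)
            if (np.diff(grp["position_cM"].to_numpy()) < 0).any():
                raise ValidationError(f"positions decrease within chromosome {chrom!r}")
        self.frame = f

    @property
    def marker_ids(self) -> list[str]:
        return self.frame["marker_id"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    def subset(self, marker_ids) -> "GeneticMap":
        keep = set(map(str, marker_ids))
        return GeneticMap(self.frame[self.frame["marker_id"].isin(keep)])

    def blocks(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (column index array, position array) in storage order."""
        out = []
        for _, grp in self.frame.groupby("chromosome", sort=False):
            out.append((grp.index.to_numpy(), grp["position_cM"].to_numpy()))
        return out


@dataclass
class QCReport:
    """Bookkeeping for marker filtering; removal reasons are disjoint."""

    n_input_markers: int
    n_removed_maf: int
    n_removed_missing: int
    n_retained: int
    per_marker: pd.DataFrame = field(repr=False)  # marker_id, maf, missing_frac, status

    def __post_init__(self) -> None:
        total = self.n_removed_maf + self.n_removed_missing + self.n_retained
        if total != self.n_input_markers:
            raise ValidationError("QC report counts are inconsistent")

    def to_tsv(self, path) -> None:
        self.per_marker.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers / writers


def _parse_call(token, row_label, col_label) -> int:
    s = str(token).strip()
    if s in _MISSING_TOKENS:
        return MISSING
    try:
        v = float(s)
    except ValueError:
        raise ValidationError(
            f"malformed genotype cell {token!r} at line {row_label!r}, marker {col_label!r}"
        ) from None
    if v not in (0.0, 1.0, 2.0):
        raise ValidationError(
            f"genotype call {token!r} out of range at line {row_label!r}, marker {col_label!r}"
        )
    return int(v)


def load_genotypes(path, format_hint: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from CSV/TSV (or VCF with ``format_hint='vcf'``).

    Tabular layout: first column line id, header row of marker ids, cells in
    {0, 1, 2, NA}.  Ids are preserved in file order.
    """
    path = str(path)
    fmt = format_hint
    if fmt is None:
        if path.endswith(".vcf") or path.endswith(".vcf.gz"):
            fmt = "vcf"
        elif path.endswith(".csv"):
            fmt = "csv"
        else:
            fmt = "tsv"
    if fmt == "vcf":
        return _load_vcf(path)
    sep = "," if fmt == "csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique(header, "marker")  # pandas would silently mangle duplicates
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    df.columns = header
    calls = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy()
    for j, mk in enumerate(df.columns):
        for i, ln in enumerate(df.index):
            calls[i, j] = _parse_call(values[i, j], ln, mk)
    return GenotypeMatrix(list(df.index), list(df.columns), calls)


def _load_vcf(path: str) -> GenotypeMatrix:
    """Import diploid GT calls from a VCF.

    Calls count the alphabetically-first allele of each biallelic site: the
    REF allele when REF sorts before ALT, else the ALT allele.  This keeps
    chip-style tables and VCF input on one coding.
    """
    line_ids: list[str] = []
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    import gzip

    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for raw in fh:
            if raw.startswith("##"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if raw.startswith("#CHROM"):
                line_ids = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise ValidationError(f"multi-allelic VCF site {vid or chrom + ':' + pos}")
            marker_ids.append(vid if vid not in (".", "") else f"{chrom}_{pos}")
            count_ref = ref.upper() <= alt.upper()
            fmt_keys = fields[8].split(":")
            gt_idx = fmt_keys.index("GT")
            row = np.empty(len(fields) - 9, dtype=np.int8)
            for i, sample in enumerate(fields[9:]):
                gt = sample.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    row[i] = MISSING
                else:
                    n_alt = sum(int(a) != 0 for a in alleles)
                    row[i] = (2 - n_alt) if count_ref else n_alt
            rows.append(row)
    calls = np.column_stack(rows) if rows else np.empty((len(line_ids), 0), dtype=np.int8)
    return GenotypeMatrix(line_ids, marker_ids, calls)


def write_genotypes(G: GenotypeMatrix, path, sep: str = "\t") -> None:
    out = G.calls.astype(object)
    out[G.calls == MISSING] = "NA"
    df = pd.DataFrame(out, index=G.line_ids, columns=G.marker_ids)
    df.index.name = "line_id"
    df.to_csv(path, sep=sep)


def load_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    return GeneticMap(df[["marker_id", "chromosome", "position_cM"]])


def write_map(gmap: GeneticMap, path) -> None:
    gmap.frame.to_csv(path, sep="\t", index=False)


def load_phenotypes(path) -> pd.DataFrame:
    """Long-format phenotype records: line_id, year, location, rep, maturity_days, yield."""
    df = pd.read_csv(path)
    required = {"line_id", "year", "location", "rep", "maturity_days", "yield"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"phenotype file lacks columns: {sorted(missing)}")
    return df


def load_crosses(path) -> list[tuple[str, str]]:
    """Candidate cross list: CSV with columns parent1, parent2."""
    df = pd.read_csv(path)
    if not {"parent1", "parent2"}.issubset(df.columns):
        raise ValidationError("cross file needs columns parent1, parent2")
    return [(str(a), str(b)) for a, b in zip(df["parent1"], df["parent2"])]


# ---------------------------------------------------------------------------
# QC


def marker_maf(G: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per marker over non-missing calls only.

    With n observed lines the allele count is 2n; a marker with no observed
    calls gets MAF 0 (it will always fail filtering via missingness).
    """
    calls = G.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    allele_sum = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, allele_sum / (2.0 * np.maximum(n_obs, 1)), 0.0)
    return np.minimum(p, 1.0 - p)


def marker_missing_fraction(G: GenotypeMatrix) -> np.ndarray:
    return (G.calls == MISSING).mean(axis=0)


def filter_markers(
    G: GenotypeMatrix, maf_min: float = 0.06, max_missing: float = 0.20
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop markers with MAF < ``maf_min`` or missing fraction > ``max_missing``.

    A marker failing both filters is booked under missingness (checked
    first), keeping the report's removal reasons disjoint.  The line set is
    never changed.
    """
    maf = marker_maf(G)
    miss = marker_missing_fraction(G)
    fail_missing = miss > max_missing
    fail_maf = (maf < maf_min) & ~fail_missing
    keep = ~(fail_missing | fail_maf)
    status = np.where(fail_missing, "removed_missing", np.where(fail_maf, "removed_maf", "retained"))
    report = QCReport(
        n_input_markers=G.n_markers,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int(fail_missing.sum()),
        n_retained=int(keep.sum()),
        per_marker=pd.DataFrame(
            {
                "marker_id": G.marker_ids,
                "maf": maf,
                "missing_frac": miss,
                "status": status,
            }
        ),
    )
    if report.n_retained == 0:
        warnings.warn("all markers removed by QC filters", stacklevel=2)
    logger.info(
        "QC: %d markers in, %d removed (missing), %d removed (MAF), %d retained",
        report.n_input_markers,
        report.n_removed_missing,
        report.n_removed_maf,
        report.n_retained,
    )
    return G.subset_markers(np.flatnonzero(keep)), report


def impute_missing(G: GenotypeMatrix, method: str = "mode", seed: int | None = None) -> GenotypeMatrix:
    """Fill missing calls marker-by-marker.

    ``mode`` takes the most frequent observed call (ties go to the lowest
    call, keeping the result deterministic); ``mean_round`` rounds the
    observed mean call half-away-from-zero.  Non-missing calls are never
    touched.  A naive stand-in for haplotype-phasing imputation.
    """
    if method not in ("mode", "mean_round"):
        raise ValueError(f"unknown imputation method {method!r}")
    calls = G.calls.copy()
    for j in range(G.n_markers):
        col = calls[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValidationError(
                f"marker {G.marker_ids[j]!r} has no observed calls; cannot impute"
            )
        if method == "mode":
            counts = np.bincount(obs, minlength=3)
            fill = int(np.argmax(counts))
        else:
            fill = int(np.floor(obs.mean() + 0.5))
        col[miss] = fill
    return GenotypeMatrix(list(G.line_ids), list(G.marker_ids), calls)


def harmonize(G: GenotypeMatrix, gmap: GeneticMap) -> tuple[GenotypeMatrix, GeneticMap]:
    """Restrict to markers present in both genotypes and map, in map order.

    Unmapped genotype markers are dropped with a logged warning so progeny
    simulation and model training stay on one panel.
    """
    geno_set = set(G.marker_ids)
    gmap2 = gmap.subset(geno_set)
    mapped = gmap2.marker_ids
    dropped = len(G.marker_ids) - len(mapped)
    if dropped:
        logger.warning("dropping %d genotyped markers absent from the genetic map", dropped)
    col = {m: i for i, m in enumerate(G.marker_ids)}
    idx = np.array([col[m] for m in mapped], dtype=int)
    return G.subset_markers(idx), gmap2
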