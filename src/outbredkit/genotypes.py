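"""Core genotype containers and file I/O.

The in-memory substrate of the whole package is a dense matrix of diploid
biallelic genotype dosages: 0 = homozygous for allele A, 1 = heterozygous,
2 = homozygous for allele B, with ``MISSING`` (-1) as an explicit sentinel
that is never imputed.  Markers carry 1-based physical coordinates and are
kept sorted by (chromosome, position).

Supported formats are whitespace-delimited PED/MAP (six leading PED
columns) and VCF 4.x (GT field only; phased and unphased separators both
accepted and treated as unphased).  Multi-allelic VCF records are dropped
with a logged count; half-missing PED genotypes become ``MISSING``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GenotypeFileError(ValueError):
    """Raised when an input genotype file is malformed or empty after filtering."""


@dataclass(frozen=True)
class MarkerMap:
    """Sorted map of biallelic SNP markers.

    ``table`` has columns ``marker_id, chromosome, position_bp, allele_a,
    allele_b``; rows are sorted by (chromosome, position_bp) and marker ids
    are unique.  Positions are 1-based physical coordinates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        required = ["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]
        missing_cols = [c for c in required if c not in t.columns]
        if missing_cols:
            raise ValueError(f"MarkerMap missing columns: {missing_cols}")
        if t["marker_id"].duplicated().any():
            dups = t.loc[t["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValueError(f"duplicate marker ids: {dups[:5]}")
        t = t.sort_values(["chromosome", "position_bp"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in t.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        object.__setattr__(self, "table", t)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions_bp(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy(dtype=np.int64)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, idx: Sequence[int]) -> "MarkerMap":
        return MarkerMap(self.table.iloc[list(idx)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Samples x markers diploid dosage matrix.

    ``calls[i, j]`` counts copies of ``allele_b`` of marker ``j`` carried by
    sample ``i`` (0/1/2), or ``MISSING``.  Column order matches ``markers``.
    """

    samples: list[str]
    markers: MarkerMap
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        bad = ~np.isin(self.calls, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError(f"invalid genotype codes at {np.argwhere(bad)[:3].tolist()}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(list(self.samples), self.markers.subset(idx), self.calls[:, idx])

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.markers, self.calls[idx, :]
        )

    def dosages(self) -> np.ndarray:
        """Calls as float with NaN for missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.markers.table.equals(other.markers.table)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class FounderPanel:
    """Homozygous genotypes of candidate inbred ancestor strains.

    Founders whose heterozygosity exceeds ``het_tolerance`` are rejected at
    construction (real inbred panels carry residual hets; heavily
    heterozygous "founders" would corrupt HMM emissions).
    """

    genotypes: GenotypeMatrix
    het_tolerance: float = 0.01

    def __post_init__(self) -> None:
        calls = self.genotypes.calls
        nonmiss = (calls != MISSING).sum(axis=1)
        het = (calls == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), 0.0)
        bad = rate > self.het_tolerance
        if bad.any():
            names = [self.genotypes.samples[i] for i in np.flatnonzero(bad)]
            raise ValueError(
                f"founders exceed het tolerance {self.het_tolerance}: {names}"
            )

    @property
    def founder_names(self) -> list[str]:
        return self.genotypes.samples

    @property
    def n_founders(self) -> int:
        return self.genotypes.n_samples

    def allele_b_prob(self) -> np.ndarray:
        """Per founder x marker probability of carrying allele B.

        Homozygous calls map to 0/1; residual het or missing calls map to
        0.5 (uninformative).
        """
        calls = self.genotypes.calls
        p = np.full(calls.shape, 0.5)
        p[calls == 0] = 0.0
        p[calls == 2] = 1.0
        return p


BREEDING_SCHEMES = (
    "random",
    "circular",
    "rotational",
    "poiley",
    "robertson",
    "igs",
    "unknown",
)


@dataclass
class ColonyPanel:
    """One colony's genotypes plus breeder metadata."""

    colony_id: str
    genotypes: GenotypeMatrix
    breeding_scheme: str = "unknown"
    colony_size: int | None = None
    sampling_date: str | None = None

    def __post_init__(self) -> None:
        if not self.colony_id:
            raise ValueError("colony_id must be non-empty")
        if self.breeding_scheme not in BREEDING_SCHEMES:
            raise ValueError(f"unknown breeding scheme {self.breeding_scheme!r}")


@dataclass
class PhenotypeTable:
    """Trait values and covariates keyed on sample id.

    ``data`` is indexed by sample id; trait columns are real-valued
    (possibly NaN), covariates may be categorical or real.
    """

    data: pd.DataFrame

    def resolve(self, g: GenotypeMatrix) -> tuple["PhenotypeTable", list[str]]:
        """Restrict to samples present in ``g``; return unmatched ids."""
        known = set(g.samples)
        matched = [s for s in self.data.index if s in known]
        unmatched = [s for s in self.data.index if s not in known]
        if unmatched:
            logger.warning("phenotype ids not in genotypes: %s", unmatched[:10])
        return PhenotypeTable(self.data.loc[matched]), unmatched

    @staticmethod
    def read_tsv(path: str, sample_col: str = "sample_id") -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t")
        if sample_col not in df.columns:
            raise GenotypeFileError(f"{path}: missing sample column {sample_col!r}")
        return PhenotypeTable(df.set_index(sample_col))

    def write_tsv(self, path: str, sample_col: str = "sample_id") -> None:
        self.data.rename_axis(sample_col).reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def _read_map(path: str) -> MarkerMap:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise GenotypeFileError(f"{path}:{lineno}: expected >=4 MAP columns")
            chrom, mid, _cm, pos = parts[0], parts[1], parts[2], parts[3]
            try:
                pos_bp = int(pos)
            except ValueError as exc:
                raise GenotypeFileError(f"{path}:{lineno}: bad position {pos!r}") from exc
            rows.append((mid, chrom, pos_bp))
    if not rows:
        raise GenotypeFileError(f"{path}: empty MAP file")
    df = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])
    # allele labels are learned from the PED body; placeholders until then
    df["allele_a"] = "?"
    df["allele_b"] = "?"
    return df  # type: ignore[return-value]  # finalized in read_pedmap


def read_pedmap(ped_path: str, map_path: str) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read PED/MAP.  Allele A/B labels are assigned per marker in
    lexicographic order of the observed alleles (PED carries no canonical
    allele order, so a stable convention keeps write -> read lossless for
    polymorphic markers); half-missing genotypes are treated as MISSING."""
    map_df = _read_map(map_path)
    n_markers = len(map_df)
    samples: list[str] = []
    geno_tokens: list[list[str]] = []
    alleles: list[set[str]] = [set() for _ in range(n_markers)]
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise GenotypeFileError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} fields, "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            geno_tokens.append(parts[6:])
            for j in range(n_markers):
                for a in (parts[6 + 2 * j], parts[7 + 2 * j]):
                    if a not in ("0", "."):
                        alleles[j].add(a)
                if len(alleles[j]) > 2:
                    raise GenotypeFileError(
                        f"{ped_path}:{lineno}: marker "
                        f"{map_df['marker_id'][j]} has >2 alleles"
                    )
    if not samples:
        raise GenotypeFileError(f"{ped_path}: no samples")
    ordered = [sorted(s) for s in alleles]
    for j, known in enumerate(ordered):
        map_df.loc[j, "allele_a"] = known[0] if len(known) >= 1 else "A"
        map_df.loc[j, "allele_b"] = known[1] if len(known) >= 2 else "B"
    rows = []
    for toks in geno_tokens:
        row = np.full(n_markers, MISSING, dtype=np.int8)
        for j in range(n_markers):
            a1, a2 = toks[2 * j], toks[2 * j + 1]
            if a1 in ("0", ".") or a2 in ("0", "."):
                continue  # half-missing -> MISSING
            b = ordered[j][1] if len(ordered[j]) == 2 else None
            row[j] = int(a1 == b) + int(a2 == b) if b is not None else 0
        rows.append(row)
    mm = MarkerMap(map_df)
    # MarkerMap sorts rows; reorder call columns accordingly
    order = [
        int(np.flatnonzero(map_df["marker_id"].to_numpy() == m)[0])
        for m in mm.marker_ids
    ]
    calls = np.vstack(rows)[:, order]
    return GenotypeMatrix(samples, mm, calls), mm


_PED_CODE = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B")}


def write_pedmap(g: GenotypeMatrix, ped_path: str, map_path: str) -> None:
    mt = g.markers.table
    with open(map_path, "w") as fh:
        for _, r in mt.iterrows():
            fh.write(f"{r.chromosome}\t{r.marker_id}\t0\t{r.position_bp}\n")
    aa = mt["allele_a"].to_numpy()
    ab = mt["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.samples):
            fields = [f"FAM{i}", sid, "0", "0", "0", "-9"]
            for j in range(g.n_markers):
                c = int(g.calls[i, j])
                if c == -1:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [aa[j], aa[j]]
                elif c == 1:
                    fields += [aa[j], ab[j]]
                else:
                    fields += [ab[j], ab[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read biallelic SNPs from a VCF via cyvcf2 (GT field only).

    Multi-allelic records are dropped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    calls = []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] == ".":
            n_dropped += 1
            continue
        gt = np.asarray(var.genotype.array())[:, :2]
        dose = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        rows.append((mid, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        calls.append(dose.astype(np.int8))
    if n_dropped:
        logger.info("dropped %d multi-allelic records from %s", n_dropped, path)
    if not rows:
        raise GenotypeFileError(f"{path}: zero biallelic markers after filtering")
    df = pd.DataFrame(
        rows, columns=["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]
    )
    mm = MarkerMap(df)
    order = [
        int(np.flatnonzero(df["marker_id"].to_numpy() == m)[0]) for m in mm.marker_ids
    ]
    mat = np.vstack(calls).T[:, order]
    return GenotypeMatrix(samples, mm, mat), mm


_VCF_GT = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    mt = g.markers.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(mt["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, r in mt.iterrows():
            gts = "\t".join(_VCF_GT[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{r.chromosome}\t{r.position_bp}\t{r.marker_id}\t"
                f"{r.allele_a}\t{r.allele_b}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotypes(path: str, format: str, map_path: str | None = None
                   ) -> tuple[GenotypeMatrix, MarkerMap]:
    """Dispatch reader.  ``format`` is 'pedmap' (requires ``map_path``) or 'vcf'."""
    if format == "pedmap":
        if map_path is None:
            if path.endswith(".ped"):
                map_path = path[:-4] + ".map"
            else:
                raise ValueError("pedmap format requires map_path")
        return read_pedmap(path, map_path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Founder alignment
# ---------------------------------------------------------------------------

def _is_ambiguous(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a.upper()) == b.upper()


def align_to_founders(
    g: GenotypeMatrix, panel: FounderPanel, ambiguous_maf_band: tuple[float, float] = (0.4, 0.6)
) -> tuple[GenotypeMatrix, FounderPanel]:
    """Restrict colony and founder genotypes to their marker intersection and
    reconcile allele labels.

    Markers with swapped A/B labels are recoded 0<->2; strand flips are
    resolved by complementing; strand-ambiguous markers (A/T, C/G) whose
    colony MAF falls in ``ambiguous_maf_band`` are dropped (orientation
    undecidable), others are oriented by matching minor alleles.
    Idempotent: aligning an already-aligned pair is a no-op.
    """
    fg = panel.genotypes
    shared = [m for m in g.markers.marker_ids if m in set(fg.markers.marker_ids)]
    if not shared:
        raise ValueError("no shared markers between genotypes and founder panel")

    g_idx = {m: i for i, m in enumerate(g.markers.marker_ids)}
    f_idx = {m: i for i, m in enumerate(fg.markers.marker_ids)}
    keep_g, keep_f, flip = [], [], []
    n_dropped_ambiguous = 0
    gt = g.markers.table
    ft = fg.markers.table
    for m in shared:
        i, j = g_idx[m], f_idx[m]
        ga, gb = str(gt["allele_a"][i]).upper(), str(gt["allele_b"][i]).upper()
        fa, fb = str(ft["allele_a"][j]).upper(), str(ft["allele_b"][j]).upper()
        if _is_ambiguous(ga, gb):
            col = g.calls[:, i]
            nm = col != MISSING
            if nm.any():
                p = (2 * (col[nm] == 2).sum() + (col[nm] == 1).sum()) / (2 * nm.sum())
            else:
                p = 0.0
            maf = min(p, 1 - p)
            if ambiguous_maf_band[0] < maf < ambiguous_maf_band[1]:
                n_dropped_ambiguous += 1
                continue
            # orient so that the colony's minor allele dosage matches the
            # founder panel's minor allele dosage
            fcol = fg.calls[:, j]
            fnm = fcol != MISSING
            fp = (
                (2 * (fcol[fnm] == 2).sum() + (fcol[fnm] == 1).sum()) / (2 * fnm.sum())
                if fnm.any()
                else 0.0
            )
            flip.append((p > 0.5) != (fp > 0.5))
            keep_g.append(i)
            keep_f.append(j)
            continue
        pairs = {
            (ga, gb): False,
            (gb, ga): True,
            (_COMPLEMENT.get(ga, "?"), _COMPLEMENT.get(gb, "?")): False,
            (_COMPLEMENT.get(gb, "?"), _COMPLEMENT.get(ga, "?")): True,
        }
        if (fa, fb) not in pairs:
            # single-allele (monomorphic) columns read from PED carry a
            # placeholder second allele; orient by the one observed allele
            col = g.calls[:, i]
            nm = col != MISSING
            observed = set(np.unique(col[nm]).tolist())
            if observed <= {0} and gb in ("B", "?"):
                if ga in (fa, _COMPLEMENT.get(fa, "?")):
                    flip.append(False)
                elif ga in (fb, _COMPLEMENT.get(fb, "?")):
                    flip.append(True)
                else:
                    logger.warning("allele mismatch at %s: %s/%s vs %s/%s", m, ga, gb, fa, fb)
                    continue
                keep_g.append(i)
                keep_f.append(j)
                continue
            logger.warning("allele mismatch at %s: %s/%s vs %s/%s", m, ga, gb, fa, fb)
            continue
        flip.append(pairs[(fa, fb)])
        keep_g.append(i)
        keep_f.append(j)
    if n_dropped_ambiguous:
        logger.info("dropped %d strand-ambiguous high-MAF markers", n_dropped_ambiguous)
    if not keep_g:
        raise ValueError("no reconcilable markers between genotypes and founder panel")

    g2 = g.subset_markers(keep_g)
    f2 = fg.subset_markers(keep_f)
    flip_arr = np.asarray(flip, dtype=bool)
    if flip_arr.any():
        cols = np.flatnonzero(flip_arr)
        gc = g2.calls.copy()
        sub = gc[:, cols]
        sub[sub == 0] = 3
        sub[sub == 2] = 0
        sub[sub == 3] = 2
        gc[:, cols] = sub
        # adopt founder allele labels for the flipped markers
        tbl = g2.markers.table.copy()
        tbl.loc[tbl.index[cols], ["allele_a", "allele_b"]] = (
            f2.markers.table.iloc[cols][["allele_a", "allele_b"]].to_numpy()
        )
        g2 = GenotypeMatrix(g2.samples, MarkerMap(tbl), gc)
    return g2, FounderPanel(f2, panel.het_tolerance)
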