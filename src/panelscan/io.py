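"""Genotype matrix and SNP map I/O.

Two text dialects are supported:

* a HapMap-dialect table (11 metadata columns followed by one two-letter
  genotype column per line), the format array genotypes are conventionally
  exchanged in;
* a plain genotype TSV (``snp_id  chromosome  position_bp  allele_a
  allele_b`` followed by one dosage column per line, ``.`` = missing).

Both map onto the same in-memory containers: :class:`SnpMap` (per-SNP id,
chromosome, 1-based physical position, the two allele codes) and
:class:`GenotypeMatrix`, whose canonical encoding is the *dosage* of
``allele_b``: 0 = homozygous ``allele_a``, 1 = heterozygous, 2 = homozygous
``allele_b``, -1 = missing.  Heterozygote letter order in HapMap input
("AG" vs "GA") is irrelevant: both map to the single heterozygous state.

Coordinates are 1-based inclusive physical positions; binning downstream
converts to 0-based half-open internally.  SNPs on chromosome ``unknown``
carry no position (stored as 0) and are excluded from positional analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DataError, FormatError

CALL_HOM_A = 0
CALL_HET = 1
CALL_HOM_B = 2
CALL_MISSING = -1

UNKNOWN_CHROM = "unknown"

MAP_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]

#: canonical HapMap metadata header (11 columns before per-line genotypes)
HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]

_NUCLEOTIDES = frozenset("ACGT")


def chromosome_sort_key(label: str):
    """Orderable key for chromosome labels: numeric first, then lexical.

    Maize chromosomes are "1".."10"; "unknown" (and any non-numeric label)
    sorts after all numeric chromosomes.
    """
    s = str(label)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


class SnpMap:
    """Per-SNP id, chromosome, 1-based position and the two allele codes."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.loc[:, MAP_COLUMNS].reset_index(drop=True)
        df["snp_id"] = df["snp_id"].astype(str)
        df["chromosome"] = df["chromosome"].astype(str)
        df["position_bp"] = df["position_bp"].astype(np.int64)
        if validate:
            self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        dup = df["snp_id"].duplicated()
        if dup.any():
            raise DataError(f"duplicate snp_id: {df.loc[dup, 'snp_id'].iloc[0]!r}")
        placed = df["chromosome"] != UNKNOWN_CHROM
        if (df.loc[placed, "position_bp"] < 1).any():
            bad = df.loc[placed & (df["position_bp"] < 1), "snp_id"].iloc[0]
            raise DataError(f"placed SNP {bad!r} has position_bp < 1")
        for col in ("allele_a", "allele_b"):
            bad = ~df[col].isin(list(_NUCLEOTIDES))
            if bad.any():
                raise DataError(
                    f"{col} of SNP {df.loc[bad, 'snp_id'].iloc[0]!r} is not one of A/C/G/T"
                )
        same = df["allele_a"] == df["allele_b"]
        if same.any():
            raise DataError(f"allele_a == allele_b for SNP {df.loc[same, 'snp_id'].iloc[0]!r}")

    @classmethod
    def from_records(cls, records) -> "SnpMap":
        return cls(pd.DataFrame(list(records), columns=MAP_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_id(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def chromosome(self) -> np.ndarray:
        return self.df["chromosome"].to_numpy()

    @property
    def position_bp(self) -> np.ndarray:
        return self.df["position_bp"].to_numpy()

    @property
    def allele_a(self) -> np.ndarray:
        return self.df["allele_a"].to_numpy()

    @property
    def allele_b(self) -> np.ndarray:
        return self.df["allele_b"].to_numpy()

    @property
    def placed(self) -> np.ndarray:
        """Boolean mask: SNPs with a known chromosome (and hence a position)."""
        return (self.df["chromosome"] != UNKNOWN_CHROM).to_numpy()

    def sort_order(self) -> np.ndarray:
        """Stable order by (chromosome, position, snp_id); numeric chromosomes first."""
        keys = [chromosome_sort_key(c) for c in self.df["chromosome"]]
        tmp = pd.DataFrame({
            "k0": [k[0] for k in keys],
            "k1": [k[1] for k in keys],
            "k2": [k[2] for k in keys],
            "pos": self.df["position_bp"],
            "id": self.df["snp_id"],
        })
        return tmp.sort_values(["k0", "k1", "k2", "pos", "id"], kind="stable").index.to_numpy()

    def take(self, index) -> "SnpMap":
        return SnpMap(self.df.iloc[np.asarray(index)].reset_index(drop=True), validate=False)


@dataclass
class GenotypeMatrix:
    """Unphased biallelic calls for lines x SNPs.

    ``calls`` is an int8 array holding the canonical dosage encoding
    (0 / 1 / 2 copies of ``allele_b``, -1 missing); the dosage view and the
    call-state view coincide by construction.
    """

    line_ids: list = field(default_factory=list)
    calls: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), dtype=np.int8))

    def __post_init__(self):
        self.line_ids = [str(x) for x in self.line_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ContractError("calls must be a 2-D lines x SNPs array")
        if self.calls.shape[0] != len(self.line_ids):
            raise ContractError(
                f"{len(self.line_ids)} line_ids but {self.calls.shape[0]} call rows"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            seen, dup = set(), None
            for lid in self.line_ids:
                if lid in seen:
                    dup = lid
                    break
                seen.add(lid)
            raise DataError(f"duplicate line id {dup!r}")
        valid = np.isin(self.calls, (-1, 0, 1, 2))
        if not valid.all():
            raise DataError("calls contain values outside {-1, 0, 1, 2}")

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def dosage(self) -> np.ndarray:
        """Integer dosage of allele_b with -1 for missing (same array as calls)."""
        return self.calls

    def dosage_float(self) -> np.ndarray:
        """Float dosage with NaN for missing calls."""
        d = self.calls.astype(float)
        d[self.calls == CALL_MISSING] = np.nan
        return d

    def line_index(self, line_id: str) -> int:
        try:
            return self.line_ids.index(str(line_id))
        except ValueError:
            raise ContractError(f"line {line_id!r} not in panel") from None

    def take_snps(self, index) -> "GenotypeMatrix":
        return GenotypeMatrix(self.line_ids, self.calls[:, np.asarray(index)])

    def take_lines(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix([self.line_ids[i] for i in index], self.calls[index])


def read_group_assignment(path) -> pd.Series:
    """Read a two-column TSV (line_id, group) into a line -> group Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("group assignment table needs line_id and group columns")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    if s.index.duplicated().any():
        raise DataError("duplicate line_id in group assignment")
    if (s.fillna("") == "").any():
        raise DataError("empty group label in group assignment")
    return s


def write_group_assignment(groups: pd.Series, path) -> None:
    pd.DataFrame({"line_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# HapMap dialect
# ---------------------------------------------------------------------------

def _canon_header(name: str) -> str:
    return name.strip().lower().rstrip("#")


def read_hapmap(path) -> tuple[SnpMap, GenotypeMatrix]:
    """Read a HapMap-dialect table into a (SnpMap, GenotypeMatrix) pair.

    Raises FormatError on a malformed metadata header (naming the offending
    column) and DataError on genotype letters outside the SNP's two alleles.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < len(HAPMAP_COLUMNS):
        raise FormatError("HapMap header has fewer than 11 metadata columns")
    for got, want in zip(cols, HAPMAP_COLUMNS):
        if _canon_header(got) != _canon_header(want):
            raise FormatError(f"HapMap header column {got!r} where {want!r} expected")
    line_ids = cols[len(HAPMAP_COLUMNS):]

    records = []
    for rs, alleles, chrom, pos in zip(df["rs#"] if "rs#" in df else df[cols[0]],
                                       df[cols[1]], df[cols[2]], df[cols[3]]):
        parts = str(alleles).split("/")
        if len(parts) != 2:
            raise FormatError(f"SNP {rs!r}: alleles field {alleles!r} is not 'X/Y'")
        p = int(pos) if str(pos).strip() not in ("", "NA") else 0
        records.append((rs, chrom, p, parts[0], parts[1]))
    smap = SnpMap.from_records(records) if records else SnpMap(
        pd.DataFrame(columns=MAP_COLUMNS).astype({"position_bp": np.int64}), validate=False)

    calls = np.full((len(line_ids), len(df)), CALL_MISSING, dtype=np.int8)
    geno = df[line_ids].to_numpy(dtype=str) if line_ids else np.zeros((len(df), 0), dtype=str)
    for s in range(len(df)):
        a = smap.allele_a[s]
        b = smap.allele_b[s]
        lut = {
            a + a: CALL_HOM_A,
            b + b: CALL_HOM_B,
            a + b: CALL_HET,
            b + a: CALL_HET,
            "NN": CALL_MISSING,
            "--": CALL_MISSING,
        }
        for l, cell in enumerate(geno[s]):
            try:
                calls[l, s] = lut[cell]
            except KeyError:
                raise DataError(
                    f"SNP {smap.snp_id[s]!r}, line {line_ids[l]!r}: "
                    f"genotype {cell!r} not in alleles {a}/{b} or NN/--"
                ) from None
    return smap, GenotypeMatrix(line_ids, calls)


def write_hapmap(smap: SnpMap, matrix: GenotypeMatrix, path) -> None:
    """Write the HapMap dialect; SNPs sorted by (chromosome, position)."""
    if len(smap) != matrix.n_snps:
        raise ContractError(f"map has {len(smap)} SNPs but matrix has {matrix.n_snps}")
    order = smap.sort_order()
    smap = smap.take(order)
    calls = matrix.calls[:, order]

    cols = {
        "rs#": smap.snp_id,
        "alleles": [f"{a}/{b}" for a, b in zip(smap.allele_a, smap.allele_b)],
        "chrom": smap.chromosome,
        "pos": smap.position_bp,
        "strand": "+",
        "assembly#": "NA",
        "center": "NA",
        "protLSID": "NA",
        "assayLSID": "NA",
        "panelLSID": "NA",
        "QCcode": "NA",
    }
    for l, lid in enumerate(matrix.line_ids):
        col = np.empty(len(smap), dtype=object)
        for s in range(len(smap)):
            a, b = smap.allele_a[s], smap.allele_b[s]
            c = calls[l, s]
            col[s] = {CALL_HOM_A: a + a, CALL_HET: a + b,
                      CALL_HOM_B: b + b, CALL_MISSING: "NN"}[c]
        cols[lid] = col
    out = pd.DataFrame(cols)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Plain genotype TSV dialect
# ---------------------------------------------------------------------------

_DOSAGE_LUT = {"0": CALL_HOM_A, "1": CALL_HET, "2": CALL_HOM_B, ".": CALL_MISSING}
_DOSAGE_STR = {CALL_HOM_A: "0", CALL_HET: "1", CALL_HOM_B: "2", CALL_MISSING: "."}


def read_genotype_table(path) -> tuple[SnpMap, GenotypeMatrix]:
    """Read the plain genotype TSV dialect (dosage entries 0/1/2/.)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[: len(MAP_COLUMNS)] != MAP_COLUMNS:
        raise FormatError(
            f"genotype table header must start with {MAP_COLUMNS}, got {cols[:5]}"
        )
    line_ids = cols[len(MAP_COLUMNS):]
    if len(df) == 0:
        smap = SnpMap(pd.DataFrame(columns=MAP_COLUMNS).astype({"position_bp": np.int64}),
                      validate=False)
        return smap, GenotypeMatrix(line_ids, np.zeros((len(line_ids), 0), dtype=np.int8))
    smap = SnpMap(df[MAP_COLUMNS].assign(position_bp=df["position_bp"].astype(np.int64)))
    calls = np.empty((len(line_ids), len(df)), dtype=np.int8)
    for l, lid in enumerate(line_ids):
        col = df[lid].to_numpy(dtype=str)
        for s, cell in enumerate(col):
            try:
                calls[l, s] = _DOSAGE_LUT[cell]
            except KeyError:
                raise DataError(
                    f"SNP {smap.snp_id[s]!r}, line {lid!r}: dosage {cell!r} "
                    "not one of 0/1/2/."
                ) from None
    return smap, GenotypeMatrix(line_ids, calls)


def write_genotype_table(smap: SnpMap, matrix: GenotypeMatrix, path) -> None:
    """Write the canonical genotype TSV; SNPs sorted by (chromosome, position)."""
    if len(smap) != matrix.n_snps:
        raise ContractError(f"map has {len(smap)} SNPs but matrix has {matrix.n_snps}")
    order = smap.sort_order()
    smap = smap.take(order)
    calls = matrix.calls[:, order]
    cols = {c: smap.df[c] for c in smap.df.columns}
    for l, lid in enumerate(matrix.line_ids):
        cols[lid] = [_DOSAGE_STR[c] for c in calls[l]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, lineterminator="\n")
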