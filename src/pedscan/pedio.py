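"""Readers and writers for pedigree, phenotype, genotype and result files.

The internal data model consists of three containers that share a single
individual ordering:

* :class:`Pedigree` — individuals with parent links, sex, household IDs,
  ordered parents-before-children within each pedigree;
* :class:`GenotypeMatrix` — minor-allele dosages (0/1/2, NaN for missing)
  for a subset of the pedigree members, plus SNP metadata;
* :class:`TraitTable` — multivariate trait values and covariates, aligned
  row-for-row with the pedigree.

All joins are by individual ID, never by file row position, because
family-study exports routinely interleave sequenced and imputed individuals.
Missing values in CSV dialects are empty fields or ``NA``; missing parents
may additionally be coded ``0`` (PLINK convention).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "TraitTable",
    "PedigreeStructureError",
    "DataFormatError",
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_traits",
    "write_traits",
    "write_scan_results",
    "read_scan_results",
]

_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", "0"}
_MISSING_FIELD = {"", "NA", "na", "NaN", "nan"}

SCAN_COLUMNS = [
    "snp_id",
    "chrom",
    "bp",
    "maf",
    "hwe_p",
    "score_stat",
    "df",
    "score_p",
    "lrt_stat",
    "lrt_p",
    "filter_flag",
]


class PedigreeStructureError(ValueError):
    """Raised when a pedigree violates its structural invariants."""


class DataFormatError(ValueError):
    """Raised when an input file cannot be interpreted under its dialect."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pedigree:
    """A collection of pedigrees ordered parents-before-children.

    ``father`` and ``mother`` hold row indices into the same ordering, with
    ``-1`` marking an absent parent.  ``founder`` is derived: both parents
    absent.  Household IDs may be ``None``; such individuals form singleton
    households.
    """

    person_id: np.ndarray
    pedigree_id: np.ndarray
    father: np.ndarray
    mother: np.ndarray
    sex: np.ndarray
    household_id: np.ndarray

    @property
    def n(self) -> int:
        return len(self.person_id)

    @property
    def founder(self) -> np.ndarray:
        return (self.father < 0) & (self.mother < 0)

    def index_of(self, ids) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.person_id)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise DataFormatError(f"unknown individual ID {exc.args[0]!r}") from None

    def pedigree_blocks(self) -> dict[str, np.ndarray]:
        """Row indices per pedigree, preserving the global ordering."""
        blocks: dict[str, list[int]] = {}
        for i, pid in enumerate(self.pedigree_id):
            blocks.setdefault(pid, []).append(i)
        return {k: np.array(v, dtype=int) for k, v in blocks.items()}

    @staticmethod
    def from_records(records: list[dict]) -> "Pedigree":
        """Validate and topologically order raw pedigree records.

        Each record needs keys ``person_id, pedigree_id, father_id,
        mother_id, sex, household_id`` (parent/household values may be
        ``None``).  Raises :class:`PedigreeStructureError` on dangling parent
        links, single-parent records, cross-pedigree parents, or cycles.
        """
        by_id: dict[str, dict] = {}
        for rec in records:
            pid = rec["person_id"]
            if pid in by_id:
                raise PedigreeStructureError(f"duplicate individual ID {pid!r}")
            by_id[pid] = rec

        for rec in records:
            fa, mo = rec["father_id"], rec["mother_id"]
            if (fa is None) != (mo is None):
                raise PedigreeStructureError(
                    f"individual {rec['person_id']!r} lists only one parent"
                )
            for parent in (fa, mo):
                if parent is None:
                    continue
                if parent not in by_id:
                    raise PedigreeStructureError(
                        f"individual {rec['person_id']!r} references missing "
                        f"parent {parent!r}"
                    )
                if by_id[parent]["pedigree_id"] != rec["pedigree_id"]:
                    raise PedigreeStructureError(
                        f"individual {rec['person_id']!r} has parent {parent!r} "
                        "in a different pedigree"
                    )

        # Kahn topological sort per pedigree, stable in file order.
        ped_order: list[str] = []
        seen_ped = set()
        for rec in records:
            if rec["pedigree_id"] not in seen_ped:
                seen_ped.add(rec["pedigree_id"])
                ped_order.append(rec["pedigree_id"])

        ordered: list[dict] = []
        for ped in ped_order:
            members = [r for r in records if r["pedigree_id"] == ped]
            pending = {r["person_id"] for r in members}
            placed: set[str] = set()
            remaining = list(members)
            while remaining:
                progress = []
                for r in remaining:
                    fa, mo = r["father_id"], r["mother_id"]
                    if (fa is None or fa in placed) and (mo is None or mo in placed):
                        progress.append(r)
                if not progress:
                    stuck = remaining[0]["person_id"]
                    raise PedigreeStructureError(
                        f"cycle detected in pedigree {ped!r} involving "
                        f"individual {stuck!r}"
                    )
                for r in progress:
                    ordered.append(r)
                    placed.add(r["person_id"])
                remaining = [r for r in remaining if r["person_id"] not in placed]
            del pending

        index = {r["person_id"]: i for i, r in enumerate(ordered)}
        n = len(ordered)
        father = np.full(n, -1, dtype=int)
        mother = np.full(n, -1, dtype=int)
        for i, r in enumerate(ordered):
            if r["father_id"] is not None:
                father[i] = index[r["father_id"]]
                mother[i] = index[r["mother_id"]]
        return Pedigree(
            person_id=np.array([r["person_id"] for r in ordered], dtype=object),
            pedigree_id=np.array([r["pedigree_id"] for r in ordered], dtype=object),
            father=father,
            mother=mother,
            sex=np.array([r.get("sex") or "unknown" for r in ordered], dtype=object),
            household_id=np.array(
                [r.get("household_id") for r in ordered], dtype=object
            ),
        )


def read_pedigree(path, dialect: str = "mendel_csv") -> Pedigree:
    """Read a pedigree file and return a validated, topologically ordered
    :class:`Pedigree`.

    ``mendel_csv`` is a header CSV with columns
    ``pedigree_id, person_id, father_id, mother_id, sex, household_id``;
    ``plink_fam`` is whitespace-separated ``FID IID PAT MAT SEX PHENO``
    (no household column).  Absent parents are empty, ``NA`` or ``0``.
    """
    records = []
    if dialect == "mendel_csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"pedigree_id", "person_id", "father_id", "mother_id"}
        if not required.issubset(df.columns):
            raise DataFormatError(
                f"pedigree CSV must contain columns {sorted(required)}"
            )
        for _, row in df.iterrows():
            records.append(
                {
                    "pedigree_id": row["pedigree_id"],
                    "person_id": row["person_id"],
                    "father_id": _parent(row["father_id"]),
                    "mother_id": _parent(row["mother_id"]),
                    "sex": _sex(row.get("sex", "")),
                    "household_id": _household(row.get("household_id", "")),
                }
            )
    elif dialect == "plink_fam":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, dtype=str, keep_default_na=False
        )
        if df.shape[1] < 5:
            raise DataFormatError("FAM file needs at least 5 columns")
        for _, row in df.iterrows():
            records.append(
                {
                    "pedigree_id": row[0],
                    "person_id": row[1],
                    "father_id": _parent(row[2]),
                    "mother_id": _parent(row[3]),
                    "sex": {"1": "male", "2": "female"}.get(row[4], "unknown"),
                    "household_id": None,
                }
            )
    else:
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    return Pedigree.from_records(records)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write a pedigree in the ``mendel_csv`` dialect."""
    rows = []
    for i in range(ped.n):
        rows.append(
            {
                "pedigree_id": ped.pedigree_id[i],
                "person_id": ped.person_id[i],
                "father_id": ped.person_id[ped.father[i]] if ped.father[i] >= 0 else "",
                "mother_id": ped.person_id[ped.mother[i]] if ped.mother[i] >= 0 else "",
                "sex": ped.sex[i],
                "household_id": ped.household_id[i] or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def _parent(tok: str) -> str | None:
    tok = tok.strip()
    return None if tok in _MISSING_TOKENS else tok


def _sex(tok: str) -> str:
    tok = str(tok).strip().lower()
    if tok in {"m", "male", "1"}:
        return "male"
    if tok in {"f", "female", "2"}:
        return "female"
    return "unknown"


def _household(tok) -> str | None:
    tok = str(tok).strip()
    return None if tok in _MISSING_FIELD else tok


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Minor-allele dosages for ``len(ids)`` individuals at ``S`` SNPs.

    ``dosages[i, s]`` counts copies of the minor allele (0/1/2) with NaN for
    missing.  ``minor_allele``/``major_allele`` record the orientation after
    load-time normalization; ``flipped`` marks SNPs whose coded allele turned
    out to be the major one and were recoded by ``2 - x``.
    """

    ids: np.ndarray
    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    minor_allele: np.ndarray
    major_allele: np.ndarray
    flipped: np.ndarray

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        return replace(self, ids=self.ids[keep], dosages=self.dosages[keep])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages[:, keep],
            snp_ids=self.snp_ids[keep],
            chrom=self.chrom[keep],
            bp=self.bp[keep],
            minor_allele=self.minor_allele[keep],
            major_allele=self.major_allele[keep],
            flipped=self.flipped[keep],
        )


def _orient_to_minor(dosages: np.ndarray, a_coded, a_other) -> tuple:
    """Flip dosages so they count the minor allele (sample frequency; ties
    keep the coded allele)."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosages, axis=0) / 2.0
    flip = p > 0.5
    dosages = dosages.copy()
    dosages[:, flip] = 2.0 - dosages[:, flip]
    minor = np.where(flip, a_other, a_coded)
    major = np.where(flip, a_coded, a_other)
    return dosages, minor.astype(object), major.astype(object), flip


def _parse_snp_name(name: str) -> tuple[str, int]:
    m = re.match(r"^(.+)-(\d+)$", name)
    if m:
        return m.group(1), int(m.group(2))
    return name, 0


def read_genotypes(path, ped: Pedigree, dialect: str = "csv_dosage") -> GenotypeMatrix:
    """Read genotypes and normalize dosages to minor-allele counts.

    ``csv_dosage``: header row of SNP IDs (convention ``chr-basepair``), one
    row per individual, first column the individual ID; entries 0/1/2 or
    NA/empty.  ``plink_bed``: path to a ``.bed`` file (or prefix) with
    ``.bim``/``.fam`` alongside.  Individuals are reordered to pedigree order;
    IDs not present in the pedigree raise an error.
    """
    if dialect == "csv_dosage":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        id_col = df.columns[0]
        snp_names = np.array(df.columns[1:], dtype=object)
        ids = df[id_col].to_numpy(dtype=object)
        raw = df.iloc[:, 1:].to_numpy(dtype=object)
        dosages = np.empty(raw.shape, dtype=float)
        for (r, c), val in np.ndenumerate(raw):
            tok = str(val).strip()
            if tok in _MISSING_FIELD:
                dosages[r, c] = np.nan
            elif tok in {"0", "1", "2"}:
                dosages[r, c] = float(tok)
            else:
                raise DataFormatError(
                    f"non-{{0,1,2}} dosage {tok!r} at row {r + 2}, "
                    f"column {snp_names[c]!r}"
                )
        chrom_bp = [_parse_snp_name(s) for s in snp_names]
        chrom = np.array([c for c, _ in chrom_bp], dtype=object)
        bp = np.array([b for _, b in chrom_bp], dtype=int)
        a_coded = np.full(len(snp_names), "A1", dtype=object)
        a_other = np.full(len(snp_names), "A2", dtype=object)
    elif dialect == "plink_bed":
        return _read_plink_bed(path, ped)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    order = _ped_order(ids, ped)
    dosages = dosages[order]
    ids = ids[order]
    dosages, minor, major, flip = _orient_to_minor(dosages, a_coded, a_other)
    return GenotypeMatrix(
        ids=ids,
        dosages=dosages,
        snp_ids=snp_names,
        chrom=chrom,
        bp=bp,
        minor_allele=minor,
        major_allele=major,
        flipped=flip,
    )


def _ped_order(ids: np.ndarray, ped: Pedigree) -> np.ndarray:
    """Permutation sorting genotype rows into pedigree order; errors on
    unknown IDs."""
    pos = {p: i for i, p in enumerate(ped.person_id)}
    for i in ids:
        if i not in pos:
            raise DataFormatError(f"unknown individual ID {i!r} in genotype file")
    return np.argsort([pos[i] for i in ids], kind="stable")


# --- PLINK BED/BIM/FAM ------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, individual-major within byte (low bits first):
# 00 = hom A1 (dosage 2 of A1), 01 = missing, 10 = het, 11 = hom A2.
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def _plink_prefix(path) -> str:
    path = str(path)
    return path[:-4] if path.endswith((".bed", ".bim", ".fam")) else path


def _read_plink_bed(path, ped: Pedigree) -> GenotypeMatrix:
    prefix = _plink_prefix(path)
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None, dtype=str, keep_default_na=False
    )
    ids = fam[1].to_numpy(dtype=object)
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None, dtype=str, keep_default_na=False
    )
    snp_names = bim[1].to_numpy(dtype=object)
    chrom = bim[0].to_numpy(dtype=object)
    bp = bim[3].to_numpy(dtype=int)
    a1 = bim[4].to_numpy(dtype=object)
    a2 = bim[5].to_numpy(dtype=object)

    n, S = len(ids), len(snp_names)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise DataFormatError("not a SNP-major PLINK BED file (bad magic bytes)")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if len(data) != bytes_per_snp * S:
        raise DataFormatError("BED file size inconsistent with BIM/FAM dimensions")
    data = data.reshape(S, bytes_per_snp)
    # unpack 2-bit codes, low bits = first individual in each byte
    codes = np.empty((S, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    dosages = _BED_DECODE[codes[:, :n]].T  # n x S, counts of A1

    order = _ped_order(ids, ped)
    dosages = dosages[order]
    ids = ids[order]
    dosages, minor, major, flip = _orient_to_minor(dosages, a1, a2)
    return GenotypeMatrix(
        ids=ids,
        dosages=dosages,
        snp_ids=snp_names,
        chrom=chrom,
        bp=bp,
        minor_allele=minor,
        major_allele=major,
        flipped=flip,
    )


def write_genotypes(
    geno: GenotypeMatrix, path, ped: Pedigree | None = None, dialect: str = "csv_dosage"
) -> None:
    """Write genotypes as ``csv_dosage`` or a PLINK BED/BIM/FAM triple.

    For ``plink_bed``, ``path`` is the file-set prefix and ``ped`` supplies
    the FAM parent/sex columns.
    """
    if dialect == "csv_dosage":
        out = pd.DataFrame(geno.dosages, columns=list(geno.snp_ids))
        out = out.map(lambda v: "" if np.isnan(v) else str(int(v)))
        out.insert(0, "person_id", geno.ids)
        out.to_csv(path, index=False)
    elif dialect == "plink_bed":
        _write_plink_bed(geno, path, ped)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def _write_plink_bed(geno: GenotypeMatrix, prefix, ped: Pedigree | None) -> None:
    prefix = _plink_prefix(prefix)
    n, S = geno.n, geno.n_snps
    # FAM
    with open(prefix + ".fam", "w") as fh:
        for pid in geno.ids:
            if ped is not None:
                i = int(ped.index_of([pid])[0])
                fa = ped.person_id[ped.father[i]] if ped.father[i] >= 0 else "0"
                mo = ped.person_id[ped.mother[i]] if ped.mother[i] >= 0 else "0"
                sex = {"male": "1", "female": "2"}.get(ped.sex[i], "0")
                fam_id = ped.pedigree_id[i]
            else:
                fa = mo = "0"
                sex = "0"
                fam_id = pid
            fh.write(f"{fam_id} {pid} {fa} {mo} {sex} -9\n")
    # BIM: A1 = minor allele (the counted one)
    with open(prefix + ".bim", "w") as fh:
        for s in range(S):
            fh.write(
                f"{geno.chrom[s]} {geno.snp_ids[s]} 0 {geno.bp[s]} "
                f"{geno.minor_allele[s]} {geno.major_allele[s]}\n"
            )
    # BED, SNP-major
    code = np.full((S, n), 1, dtype=np.uint8)  # 01 = missing
    d = geno.dosages.T
    code[d == 2.0] = 0b00
    code[d == 1.0] = 0b10
    code[d == 0.0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((S, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = code
    packed = np.zeros((S, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Traits and covariates
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Trait and covariate values aligned row-for-row with a pedigree.

    NaN encodes missing entries.  ``trait_groups`` maps a longitudinal group
    name (e.g. ``SBP``) to the indices of its time-point columns
    (``SBP_1 .. SBP_4``); non-longitudinal traits form singleton groups.
    """

    ids: np.ndarray
    trait_names: list[str]
    traits: np.ndarray
    covariate_names: list[str]
    covariates: np.ndarray
    trait_groups: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.trait_groups:
            self.trait_groups = _infer_groups(self.trait_names)

    @property
    def n(self) -> int:
        return self.traits.shape[0]

    @property
    def n_traits(self) -> int:
        return self.traits.shape[1]


def _infer_groups(names: list[str]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for j, name in enumerate(names):
        m = re.match(r"^(.*)_(\d+)$", name)
        groups.setdefault(m.group(1) if m else name, []).append(j)
    return groups


def read_traits(
    path,
    ped: Pedigree,
    trait_names: list[str],
    covariate_names: list[str] | None = None,
) -> TraitTable:
    """Read a phenotype CSV (first column ``person_id``) aligned to ``ped``.

    Pedigree members absent from the file get all-NaN rows; file rows whose
    ID is not in the pedigree raise an error.
    """
    covariate_names = covariate_names or []
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True)
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    idx = ped.index_of(df[id_col].to_numpy(dtype=object))
    traits = np.full((ped.n, len(trait_names)), np.nan)
    covs = np.full((ped.n, len(covariate_names)), np.nan)
    for j, name in enumerate(trait_names):
        if name not in df.columns:
            raise DataFormatError(f"trait column {name!r} absent from {path}")
        traits[idx, j] = df[name].to_numpy(dtype=float)
    for j, name in enumerate(covariate_names):
        if name not in df.columns:
            raise DataFormatError(f"covariate column {name!r} absent from {path}")
        covs[idx, j] = df[name].to_numpy(dtype=float)
    return TraitTable(
        ids=ped.person_id.copy(),
        trait_names=list(trait_names),
        traits=traits,
        covariate_names=list(covariate_names),
        covariates=covs,
    )


def write_traits(table: TraitTable, path) -> None:
    df = pd.DataFrame({"person_id": table.ids})
    for j, name in enumerate(table.trait_names):
        df[name] = table.traits[:, j]
    for j, name in enumerate(table.covariate_names):
        df[name] = table.covariates[:, j]
    df.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Scan results
# ---------------------------------------------------------------------------


def write_scan_results(result, path) -> None:
    """Write a :class:`~pedscan.assoc.ScanResult` as a tab-separated table.

    Columns: snp_id, chrom, bp, maf, hwe_p, score_stat, df, score_p,
    lrt_stat, lrt_p, filter_flag.  LRT fields are empty unless the SNP was
    refined; all p/statistic fields are empty for filtered SNPs.  The header
    is preceded by ``#`` metadata lines carrying scan-level numbers
    (m_tested, thresholds, genomic inflation).
    """
    df = result.table.copy()
    buf = io.StringIO()
    for key, val in result.metadata.items():
        buf.write(f"# {key}={val}\n")
    df.to_csv(buf, sep="\t", index=False, na_rep="", float_format="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_scan_results(path) -> tuple[pd.DataFrame, dict]:
    """Read back a scan-result TSV; returns (table, metadata)."""
    metadata = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            metadata[key.strip()] = val
            body_start = i + 1
        else:
            break
    df = pd.read_csv(
        io.StringIO("".join(lines[body_start:])),
        sep="\t",
        dtype={"snp_id": str, "chrom": str, "filter_flag": str},
        float_precision="round_trip",
    )
    df["filter_flag"] = df["filter_flag"].fillna("")
    return df, metadata
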