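"""Diploid multilocus genotype tables and their sample hierarchy.

The universal input of the pipeline is a :class:`GenotypeMatrix`: ``N``
individuals scored at ``L`` codominant loci, two integer allele codes per
locus (microsatellite fragment sizes or arbitrary positive integers), with
a per-cell missing mask.  Samples carry a four-level geographic hierarchy
(site < island < ecoregion < province).

Supported on-disk dialects: GenePop 4.x, STRUCTURE two-row-per-individual,
and a long CSV.  Missing data is coded ``0``/``000`` in GenePop and
STRUCTURE files and as empty cells in CSV.  Half-missing calls (one allele
typed, the other not) are promoted to fully missing with a warning, since
every downstream estimator treats a locus as typed-or-not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIERARCHY_LEVELS = ("site", "island", "ecoregion", "province")


class GenotypeFormatError(ValueError):
    """Malformed genotype file (bad line, odd allele count, bad code)."""


class GenotypeValidationError(ValueError):
    """Structurally invalid genotype matrix or hierarchy."""


@dataclass
class GenotypeMatrix:
    """N diploid individuals x L loci with integer allele codes.

    ``alleles`` is an ``(N, L, 2)`` integer array; cells where
    ``missing_mask`` is True hold 0 in both slots.  Allele codes are
    carried verbatim (no binning of fragment sizes).
    """

    individual_ids: list[str]
    locus_names: list[str]
    alleles: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise GenotypeValidationError("alleles must have shape (N, L, 2)")
        n, l, _ = self.alleles.shape
        if n < 1 or l < 1:
            raise GenotypeValidationError("need N >= 1 individuals and L >= 1 loci")
        if len(self.individual_ids) != n:
            raise GenotypeValidationError("individual_ids length mismatch")
        if len(self.locus_names) != l:
            raise GenotypeValidationError("locus_names length mismatch")
        if len(set(self.individual_ids)) != n:
            raise GenotypeValidationError("duplicate individual id")
        if len(set(self.locus_names)) != l:
            raise GenotypeValidationError("duplicate locus name")
        if self.missing_mask is None:
            self.missing_mask = (self.alleles <= 0).any(axis=2)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (n, l):
            raise GenotypeValidationError("missing_mask must have shape (N, L)")
        # promote half-calls: a cell is typed only if both slots are positive
        half = (self.alleles > 0).any(axis=2) & (self.alleles <= 0).any(axis=2)
        half &= ~self.missing_mask
        if half.any():
            logger.warning(
                "promoted %d half-missing calls to fully missing", int(half.sum())
            )
            self.missing_mask |= half
        self.alleles = np.where(self.missing_mask[:, :, None], 0, self.alleles)
        if (self.alleles[~self.missing_mask] <= 0).any():
            raise GenotypeValidationError("allele codes must be positive integers")

    # -- convenience -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def subset(self, indices) -> "GenotypeMatrix":
        """Row subset preserving order of ``indices``."""
        idx = np.asarray(indices)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            list(self.locus_names),
            self.alleles[idx].copy(),
            self.missing_mask[idx].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.locus_names == other.locus_names
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.array_equal(
                np.sort(np.where(self.missing_mask[:, :, None], 0, self.alleles), axis=2),
                np.sort(np.where(other.missing_mask[:, :, None], 0, other.alleles), axis=2),
            )
        )


@dataclass
class SampleHierarchy:
    """Per-individual site/island/ecoregion/province labels.

    The mapping site -> island -> ecoregion -> province must be a function
    (no site in two islands).  When only sites are known the higher levels
    default to the site label.
    """

    site: list[str]
    island: list[str] = None  # type: ignore[assignment]
    ecoregion: list[str] = None  # type: ignore[assignment]
    province: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.site = [str(s) for s in self.site]
        if self.island is None:
            self.island = list(self.site)
        if self.ecoregion is None:
            self.ecoregion = list(self.island)
        if self.province is None:
            self.province = list(self.ecoregion)
        n = len(self.site)
        for lev in HIERARCHY_LEVELS[1:]:
            if len(getattr(self, lev)) != n:
                raise GenotypeValidationError(f"hierarchy level {lev} length mismatch")
        for child, parent in zip(HIERARCHY_LEVELS[:-1], HIERARCHY_LEVELS[1:]):
            mapping: dict[str, str] = {}
            for c, p in zip(getattr(self, child), getattr(self, parent)):
                if mapping.setdefault(c, p) != p:
                    raise GenotypeValidationError(
                        f"{child} {c!r} mapped to two different {parent}s"
                    )

    def __len__(self) -> int:
        return len(self.site)

    def subset(self, indices) -> "SampleHierarchy":
        idx = list(indices)
        return SampleHierarchy(
            [self.site[i] for i in idx],
            [self.island[i] for i in idx],
            [self.ecoregion[i] for i in idx],
            [self.province[i] for i in idx],
        )

    def to_frame(self, individual_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": individual_ids,
                "site": self.site,
                "island": self.island,
                "ecoregion": self.ecoregion,
                "province": self.province,
            }
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

FORMATS = ("genepop", "structure2row", "csv")


def read_genotypes(path, format: str, metadata=None):
    """Read a genotype table; returns ``(GenotypeMatrix, SampleHierarchy)``.

    ``format`` is one of ``genepop``, ``structure2row``, ``csv``.  GenePop
    "pop" blocks and the STRUCTURE population column populate the *site*
    level; higher levels come from an optional sidecar ``metadata`` table
    (CSV path or DataFrame with columns individual, site, island,
    ecoregion, province).
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    reader = {"genepop": _read_genepop, "structure2row": _read_structure, "csv": _read_csv}
    gm, hier = reader[format](path)
    if metadata is not None:
        hier = _apply_metadata(gm, hier, metadata)
    return gm, hier


def write_genotypes(gm: GenotypeMatrix, hierarchy: SampleHierarchy, path, format: str) -> None:
    """Write a genotype table re-readable by :func:`read_genotypes`."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if gm.n_loci == 0:
        raise GenotypeValidationError("refusing to write a matrix with zero loci")
    if hierarchy is None:
        hierarchy = SampleHierarchy(["pop1"] * gm.n_individuals)
    if len(hierarchy) != gm.n_individuals:
        raise GenotypeValidationError("hierarchy / matrix size mismatch")
    writer = {"genepop": _write_genepop, "structure2row": _write_structure, "csv": _write_csv}
    writer[format](gm, hierarchy, path)


def summarize_missing(gm: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-individual and per-locus missing-data rates, both in [0, 1]."""
    per_ind = pd.Series(
        gm.missing_mask.mean(axis=1), index=gm.individual_ids, name="missing_rate"
    )
    per_locus = pd.Series(
        gm.missing_mask.mean(axis=0), index=gm.locus_names, name="missing_rate"
    )
    return per_ind, per_locus


# -- GenePop ----------------------------------------------------------------


def _read_genepop(path):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise GenotypeFormatError("empty GenePop file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus list: one per line, or comma-separated on one line
        part = lines[i].strip()
        if part:
            loci.extend(x.strip() for x in part.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise GenotypeFormatError("no 'pop' separator found")
    ids: list[str] = []
    sites: list[str] = []
    rows: list[list[int]] = []
    pop_idx = 0
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        if raw.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in raw:
            raise GenotypeFormatError(f"line {lineno + 1}: missing ',' separator")
        label, geno = raw.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise GenotypeFormatError(
                f"line {lineno + 1}: expected {len(loci)} loci, got {len(fields)}"
            )
        alleles: list[int] = []
        for f in fields:
            if len(f) not in (4, 6) or not f.isdigit():
                raise GenotypeFormatError(
                    f"line {lineno + 1}: bad diploid code {f!r} (need 4 or 6 digits)"
                )
            w = len(f) // 2
            alleles.extend((int(f[:w]), int(f[w:])))
        ids.append(label.strip())
        sites.append(f"pop{pop_idx}")
        rows.append(alleles)
    if not rows:
        raise GenotypeFormatError("no individuals found")
    arr = np.array(rows, dtype=np.int32).reshape(len(rows), len(loci), 2)
    gm = GenotypeMatrix(ids, loci, arr)
    return gm, SampleHierarchy(sites)


def _write_genepop(gm: GenotypeMatrix, hierarchy: SampleHierarchy, path) -> None:
    if int(gm.alleles.max(initial=0)) > 999:
        raise GenotypeFormatError("allele code exceeds 3 digits; cannot encode GenePop")
    with open(path, "w") as fh:
        fh.write("matryoshka genotype export\n")
        for loc in gm.locus_names:
            fh.write(f"{loc}\n")
        current = object()
        for i in range(gm.n_individuals):
            if hierarchy.site[i] != current:
                fh.write("pop\n")
                current = hierarchy.site[i]
            codes = " ".join(
                f"{gm.alleles[i, l, 0]:03d}{gm.alleles[i, l, 1]:03d}"
                for l in range(gm.n_loci)
            )
            fh.write(f"{gm.individual_ids[i]} , {codes}\n")


# -- STRUCTURE two-row ------------------------------------------------------


def _read_structure(path):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeFormatError("empty structure file")
    first = lines[0].split()
    # header = locus names only (no id/pop columns) when the token count is
    # two short of the data rows
    body_start = 0
    loci: list[str] | None = None
    if lines[1:] and len(first) == len(lines[1].split()) - 2:
        loci = first
        body_start = 1
    body = lines[body_start:]
    if len(body) % 2 != 0:
        raise GenotypeFormatError("structure2row file must have two rows per individual")
    n_cols = len(body[0].split())
    if loci is None:
        loci = [f"locus{j + 1}" for j in range(n_cols - 2)]
    n_loci = len(loci)
    ids, sites, rows = [], [], []
    for k in range(0, len(body), 2):
        r1, r2 = body[k].split(), body[k + 1].split()
        if len(r1) != n_loci + 2 or len(r2) != n_loci + 2:
            raise GenotypeFormatError(f"row {k + body_start + 1}: wrong column count")
        if r1[0] != r2[0]:
            raise GenotypeFormatError(
                f"row {k + body_start + 1}: the two rows of {r1[0]!r} do not pair"
            )
        try:
            a1 = [int(x) for x in r1[2:]]
            a2 = [int(x) for x in r2[2:]]
        except ValueError as exc:
            raise GenotypeFormatError(f"row {k + body_start + 1}: non-integer allele") from exc
        ids.append(r1[0])
        sites.append(r1[1])
        rows.append(np.column_stack([a1, a2]))
    arr = np.stack(rows).astype(np.int32)
    gm = GenotypeMatrix(ids, loci, arr)
    return gm, SampleHierarchy(sites)


def _write_structure(gm: GenotypeMatrix, hierarchy: SampleHierarchy, path) -> None:
    site_code = {s: i + 1 for i, s in enumerate(dict.fromkeys(hierarchy.site))}
    with open(path, "w") as fh:
        fh.write(" ".join(gm.locus_names) + "\n")
        for i in range(gm.n_individuals):
            for slot in (0, 1):
                vals = " ".join(str(gm.alleles[i, l, slot]) for l in range(gm.n_loci))
                fh.write(f"{gm.individual_ids[i]} {site_code[hierarchy.site[i]]} {vals}\n")


# -- long CSV ---------------------------------------------------------------

_CSV_COLS = ["individual", "site", "island", "ecoregion", "province", "locus", "allele1", "allele2"]


def _read_csv(path):
    df = pd.read_csv(path, dtype={"individual": str, "locus": str})
    missing_cols = [c for c in _CSV_COLS if c not in df.columns]
    if missing_cols:
        raise GenotypeFormatError(f"CSV missing columns: {missing_cols}")
    ids = list(dict.fromkeys(df["individual"]))
    loci = list(dict.fromkeys(df["locus"]))
    n, l = len(ids), len(loci)
    iidx = {v: i for i, v in enumerate(ids)}
    lidx = {v: i for i, v in enumerate(loci)}
    arr = np.zeros((n, l, 2), dtype=np.int32)
    seen = np.zeros((n, l), dtype=bool)
    meta: dict[str, tuple] = {}
    for row in df.itertuples(index=False):
        i, j = iidx[row.individual], lidx[row.locus]
        if seen[i, j]:
            raise GenotypeFormatError(
                f"duplicate cell for individual {row.individual!r} locus {row.locus!r}"
            )
        seen[i, j] = True
        a1 = 0 if pd.isna(row.allele1) else int(row.allele1)
        a2 = 0 if pd.isna(row.allele2) else int(row.allele2)
        arr[i, j] = (a1, a2)
        meta[row.individual] = (str(row.site), str(row.island), str(row.ecoregion), str(row.province))
    gm = GenotypeMatrix(ids, loci, arr)
    hier = SampleHierarchy(
        [meta[i][0] for i in ids],
        [meta[i][1] for i in ids],
        [meta[i][2] for i in ids],
        [meta[i][3] for i in ids],
    )
    return gm, hier


def _write_csv(gm: GenotypeMatrix, hierarchy: SampleHierarchy, path) -> None:
    recs = []
    for i in range(gm.n_individuals):
        for l in range(gm.n_loci):
            a1, a2 = (None, None) if gm.missing_mask[i, l] else tuple(int(x) for x in gm.alleles[i, l])
            recs.append(
                (
                    gm.individual_ids[i],
                    hierarchy.site[i],
                    hierarchy.island[i],
                    hierarchy.ecoregion[i],
                    hierarchy.province[i],
                    gm.locus_names[l],
                    a1,
                    a2,
                )
            )
    pd.DataFrame(recs, columns=_CSV_COLS).to_csv(path, index=False)


def _apply_metadata(gm: GenotypeMatrix, hier: SampleHierarchy, metadata) -> SampleHierarchy:
    if not isinstance(metadata, pd.DataFrame):
        metadata = pd.read_csv(metadata, dtype=str)
    metadata = metadata.set_index("individual")
    levels = {lev: [] for lev in HIERARCHY_LEVELS}
    for i, ind in enumerate(gm.individual_ids):
        if ind in metadata.index:
            row = metadata.loc[ind]
            prev = None
            for lev in HIERARCHY_LEVELS:
                val = row.get(lev)
                if val is None or pd.isna(val):
                    val = prev if prev is not None else hier.site[i]
                levels[lev].append(str(val))
                prev = str(val)
        else:
            levels["site"].append(hier.site[i])
            for lev in HIERARCHY_LEVELS[1:]:
                levels[lev].append(hier.site[i])
    return SampleHierarchy(**levels)
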