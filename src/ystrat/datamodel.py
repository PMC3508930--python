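"""Core domain types and file formats.

The package analyses two representations of Y-chromosomal data:

* per-individual haplotype tables — one record per sampled man carrying a
  population label, an optional group label, a haplogroup call and integer
  repeat counts at 17 Y-STR loci (tab-delimited text on disk);
* population x haplogroup count matrices with per-population sample sizes
  (CSV on disk), the unit of all frequency-based analyses.

Counts can be reconstructed from printed percentage tables via
:func:`counts_from_frequencies`; the row-sum checksum makes transcription
errors surface immediately.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HAPLOGROUPS",
    "DEFAULT_LOCI",
    "MISSING",
    "FormatError",
    "ChecksumError",
    "HaplotypeRecord",
    "HaplotypeTable",
    "CountMatrix",
    "Grouping",
    "DistanceMatrix",
    "read_haplotype_table",
    "write_haplotype_table",
    "counts_from_frequencies",
    "pool_counts",
    "write_result_json",
]

#: The 21-haplogroup inventory of the Tamil Nadu survey, in table order.
HAPLOGROUPS = (
    "C-M130", "E-M96", "F-M89", "G-M201", "H-M69", "H1-M52", "H1a-M197",
    "H2-Apt", "J-M304", "J2-M172", "J2a1-M47", "J2a3-M68", "K-M9", "L1-M27",
    "L3-M357", "O-M175", "P-M45", "Q-M242", "R-M207", "R1a1-M17", "R2-M124",
)

#: 17 single-copy Y-STR loci (Yfiler panel plus two multiplex loci, minus the
#: multi-copy DYS385a/b pair, which cannot be assigned unambiguously).
DEFAULT_LOCI = (
    "DYS19", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS437", "DYS438", "DYS439", "DYS448", "DYS456", "DYS458", "DYS635",
    "GATA_H4", "DYS388", "DYS426",
)

#: Sentinel for a missing repeat count.
MISSING = -1

_ALLELE_MIN, _ALLELE_MAX = 5, 50


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ChecksumError(ValueError):
    """Reconstructed counts do not sum to the declared sample size."""

    def __init__(self, msg: str, residual: int):
        super().__init__(msg)
        self.residual = residual


@dataclass(frozen=True)
class HaplotypeRecord:
    """One sampled Y chromosome."""

    sample_id: str
    population: str
    haplogroup: str
    str_alleles: tuple[int, ...]
    group: str | None = None

    def __post_init__(self):
        for a in self.str_alleles:
            if a != MISSING and not (_ALLELE_MIN <= a <= _ALLELE_MAX):
                raise ValueError(
                    f"allele {a} for {self.sample_id} outside "
                    f"[{_ALLELE_MIN}, {_ALLELE_MAX}] and not missing"
                )

    @property
    def complete(self) -> bool:
        return MISSING not in self.str_alleles


class HaplotypeTable:
    """Ordered collection of :class:`HaplotypeRecord` sharing one locus panel."""

    def __init__(self, records: Iterable[HaplotypeRecord],
                 loci: Sequence[str] = DEFAULT_LOCI):
        self.records: list[HaplotypeRecord] = list(records)
        self.loci: tuple[str, ...] = tuple(loci)
        for r in self.records:
            if len(r.str_alleles) != len(self.loci):
                raise FormatError(
                    f"record {r.sample_id}: expected {len(self.loci)} loci, "
                    f"got {len(r.str_alleles)}"
                )
        census = self.census
        for pop, n in census.items():
            if n < 1:
                raise ValueError(f"population {pop} has no records")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.population, None)
        return list(seen)

    @property
    def census(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.population] = out.get(r.population, 0) + 1
        return out

    def alleles(self, complete_only: bool = True) -> np.ndarray:
        """(n, L) integer allele matrix; optionally drop incomplete records."""
        recs = [r for r in self.records if r.complete] if complete_only else self.records
        return np.array([r.str_alleles for r in recs], dtype=np.int64)

    def subset(self, populations: Iterable[str] | None = None,
               haplogroup: str | None = None,
               complete_only: bool = False) -> "HaplotypeTable":
        pops = set(populations) if populations is not None else None
        recs = [
            r for r in self.records
            if (pops is None or r.population in pops)
            and (haplogroup is None or r.haplogroup == haplogroup)
            and (not complete_only or r.complete)
        ]
        return HaplotypeTable(recs, self.loci)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": r.sample_id, "population": r.population,
             "group": r.group or "", "haplogroup": r.haplogroup,
             **dict(zip(self.loci, r.str_alleles))}
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def count_matrix(self, haplogroups: Sequence[str] | None = None) -> "CountMatrix":
        """Tabulate haplogroup counts per population."""
        hgs = list(haplogroups) if haplogroups is not None else sorted(
            {r.haplogroup for r in self.records})
        pops = self.populations
        counts = np.zeros((len(pops), len(hgs)), dtype=np.int64)
        pi = {p: i for i, p in enumerate(pops)}
        hi = {h: j for j, h in enumerate(hgs)}
        for r in self.records:
            counts[pi[r.population], hi[r.haplogroup]] += 1
        return CountMatrix(pops, hgs, counts)


class CountMatrix:
    """Populations x haplogroups integer counts; each row sums to its N."""

    def __init__(self, populations: Sequence[str], haplogroups: Sequence[str],
                 counts: np.ndarray):
        self.populations = list(populations)
        self.haplogroups = list(haplogroups)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.shape != (len(self.populations), len(self.haplogroups)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n(self) -> np.ndarray:
        """Per-population sample sizes."""
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self, percent: bool = True) -> np.ndarray:
        f = self.counts / self.n[:, None]
        return f * 100.0 if percent else f

    def row(self, population: str) -> np.ndarray:
        return self.counts[self.populations.index(population)]

    def column(self, haplogroup: str) -> np.ndarray:
        return self.counts[:, self.haplogroups.index(haplogroup)]

    def subset_rows(self, populations: Iterable[str]) -> "CountMatrix":
        idx = [self.populations.index(p) for p in populations]
        return CountMatrix([self.populations[i] for i in idx],
                           self.haplogroups, self.counts[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.populations,
                          columns=self.haplogroups)
        df.insert(0, "N", self.n)
        df.index.name = "population"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, index_col="population")
        if "N" not in df.columns:
            raise FormatError("count matrix CSV must carry an 'N' column")
        n = df.pop("N").to_numpy()
        m = cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.int64))
        if not np.array_equal(m.n, n):
            raise ChecksumError("row sums do not match declared N",
                                int(np.abs(m.n - n).sum()))
        return m


@dataclass(frozen=True)
class Grouping:
    """A named mapping population -> group label."""

    name: str
    assignment: Mapping[str, str]
    groups: tuple[str, ...] = field(default=())

    def __post_init__(self):
        groups = self.groups or tuple(dict.fromkeys(self.assignment.values()))
        object.__setattr__(self, "groups", groups)
        if not groups:
            raise ValueError("grouping must define at least one group")
        missing = set(self.assignment.values()) - set(groups)
        if missing:
            raise ValueError(f"labels {missing} not in declared group list")

    def __getitem__(self, population: str) -> str:
        try:
            return self.assignment[population]
        except KeyError:
            raise KeyError(f"population {population!r} is not mapped "
                           f"in grouping {self.name!r}") from None

    def members(self, group: str) -> list[str]:
        return [p for p, g in self.assignment.items() if g == group]

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "Grouping":
        """Two-column whitespace/tab text: population<TAB>group."""
        assignment = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.rsplit(None, 1)
                if len(parts) != 2:
                    raise FormatError(f"expected 'population<TAB>group': {line!r}")
                assignment[parts[0].strip()] = parts[1].strip()
        return cls(name or str(path), assignment)


class DistanceMatrix:
    """Symmetric non-negative pairwise distances with a metric tag."""

    def __init__(self, labels: Sequence[str], values: np.ndarray,
                 metric: str = "unknown"):
        self.labels = list(labels)
        self.values = np.asarray(values, dtype=float)
        self.metric = metric
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal is not zero")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels,
                     columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, metric: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float), metric)


# ---------------------------------------------------------------------------
# haplotype table I/O (tab-delimited, '#' comments, UTF-8)

_META_COLS = ("sample", "population", "group", "haplogroup")
_MISSING_TOKENS = {".", "", "na", "nan"}


def read_haplotype_table(path, loci: Sequence[str] | None = None) -> HaplotypeTable:
    """Read a tab-delimited per-individual haplotype table.

    The header must name ``sample``, ``population``, ``haplogroup``, an
    optional ``group``, and exactly 17 locus columns (or the panel passed as
    *loci*). Missing alleles may be encoded as ``.``/``NA`` and are kept,
    flagged with the missing sentinel — they are never silently dropped.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(fh)]
    lines = [(no, ln) for no, ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0][1].split("\t")
    for col in ("sample", "population", "haplogroup"):
        if col not in header:
            raise FormatError(f"{path}: header missing column {col!r}")
    locus_cols = [c for c in header if c not in _META_COLS]
    expect = list(loci) if loci is not None else list(DEFAULT_LOCI)
    if len(locus_cols) != len(expect):
        raise FormatError(
            f"{path}: expected {len(expect)} loci, found {len(locus_cols)}")
    col_idx = {c: header.index(c) for c in header}
    records = []
    for no, ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}:{no}: expected {len(header)} fields, "
                              f"got {len(fields)}")
        alleles = []
        for c in locus_cols:
            tok = fields[col_idx[c]].strip()
            if tok.lower() in _MISSING_TOKENS:
                alleles.append(MISSING)
                continue
            try:
                alleles.append(int(tok))
            except ValueError:
                raise FormatError(
                    f"{path}:{no}: non-integer allele {tok!r} at locus {c}"
                ) from None
        grp = fields[col_idx["group"]].strip() if "group" in col_idx else ""
        records.append(HaplotypeRecord(
            sample_id=fields[col_idx["sample"]].strip(),
            population=fields[col_idx["population"]].strip(),
            haplogroup=fields[col_idx["haplogroup"]].strip(),
            str_alleles=tuple(alleles),
            group=grp or None,
        ))
    return HaplotypeTable(records, loci=tuple(locus_cols))


def write_haplotype_table(table: HaplotypeTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(("sample", "population", "group", "haplogroup")
                           + table.loci) + "\n")
        for r in table.records:
            alleles = ["." if a == MISSING else str(a) for a in r.str_alleles]
            fh.write("\t".join([r.sample_id, r.population, r.group or "",
                                r.haplogroup] + alleles) + "\n")


# ---------------------------------------------------------------------------
# count reconstruction from printed percentages

def counts_from_frequencies(freq_percent: Sequence[float], n: int,
                            tol: int = 0) -> np.ndarray:
    """Reconstruct integer counts from printed percentages.

    counts = nearest integer (ties to even) of ``freq * n / 100``. Raises
    :class:`ChecksumError` when the row sum misses *n* by more than *tol* —
    printed 2-decimal frequencies of true integer counts always reconstruct
    exactly, so a failure signals a transcription mistake.
    """
    f = np.asarray(freq_percent, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if (f < 0).any() or (f > 100).any():
        raise ValueError("frequencies must lie in [0, 100]")
    counts = np.rint(f * n / 100.0).astype(np.int64)
    residual = int(counts.sum() - n)
    if abs(residual) > tol:
        raise ChecksumError(
            f"reconstructed counts sum to {counts.sum()}, expected {n}",
            residual)
    return counts


def pool_counts(m: CountMatrix, g: Grouping) -> CountMatrix:
    """Column-wise sum of member rows per group; preserves the total N."""
    for p in m.populations:
        g[p]  # raises KeyError naming the population
    rows = []
    labels = [grp for grp in g.groups
              if any(g[p] == grp for p in m.populations)]
    for grp in labels:
        idx = [i for i, p in enumerate(m.populations) if g[p] == grp]
        rows.append(m.counts[idx].sum(axis=0))
    return CountMatrix(labels, m.haplogroups, np.array(rows))


def write_result_json(payload: dict, path, kind: str) -> None:
    doc = {"schema": "ystrat/1", "kind": kind, **payload}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")
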