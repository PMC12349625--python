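"""Data model and I/O for diploid codominant SSR genotype datasets.

Genotypes are unordered pairs of allele labels (canonically integer
fragment sizes in base pairs); the integer 0 (or an empty cell) is the
missing-data sentinel and never counts as an allele.  A call is either
fully observed or fully missing — half-calls are rejected rather than
coerced, because they usually indicate a genotyping or transcription
error upstream.

Two interchange formats are supported:

* a GenAlEx-dialect CSV (three header rows: counts, titles, column
  names; then one row per individual with two allele columns per locus);
* a long-format TSV with columns ``sample, population, locus,
  allele1, allele2``.

Population order is the order of first appearance in the file and locus
order is column order; every downstream report preserves these orders.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = 0

__all__ = [
    "MISSING",
    "SSRFormatError",
    "SSRValidationError",
    "NoDataError",
    "GenotypeMatrix",
    "PopulationView",
    "read_genalex",
    "write_genalex",
    "read_long_tsv",
    "write_long_tsv",
    "allele_frequencies",
]


class SSRFormatError(ValueError):
    """Malformed input file (bad header, inconsistent counts, ...)."""


class SSRValidationError(ValueError):
    """Structurally valid file with ill-formed content (e.g. half-calls)."""


class NoDataError(ValueError):
    """A (population, locus) cell has no non-missing calls."""

    def __init__(self, population: str, locus: str):
        self.population = population
        self.locus = locus
        super().__init__(f"no data at locus {locus!r} in population {population!r}")


def _normalize_allele(value: object) -> int:
    """Coerce an allele token to its canonical integer label (0 = missing)."""
    if value is None:
        return MISSING
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return MISSING
    try:
        out = int(value)
    except (TypeError, ValueError):
        raise SSRValidationError(f"allele label {value!r} is not an integer") from None
    if out < 0:
        raise SSRValidationError(f"allele label {out} is negative")
    return out


@dataclass(frozen=True)
class PopulationView:
    """Per-population sample counts: total individuals and usable calls per locus."""

    population: str
    n_total: int
    n_per_locus: dict[str, int]


class GenotypeMatrix:
    """Diploid multi-locus genotypes with population labels.

    Parameters
    ----------
    individuals
        Ordered sample identifiers (unique).
    loci
        Ordered locus identifiers (unique).
    pop_of
        Mapping from individual to population label.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``; each pair
        is an unordered genotype, ``(0, 0)`` meaning missing.  Pairs are
        stored sorted so that equal datasets compare equal regardless of
        the order alleles were written in.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[str],
        pop_of: Mapping[str, str],
        calls: np.ndarray,
    ):
        self.individuals = tuple(str(i) for i in individuals)
        self.loci = tuple(str(l) for l in loci)
        if len(set(self.individuals)) != len(self.individuals):
            raise SSRValidationError("duplicate individual IDs")
        if len(set(self.loci)) != len(self.loci):
            raise SSRValidationError("duplicate locus IDs")
        if len(self.loci) < 1:
            raise SSRValidationError("at least one locus required")
        if len(self.individuals) < 1:
            raise SSRValidationError("at least one individual required")
        self.pop_of = {str(k): str(v) for k, v in pop_of.items()}
        missing_pop = [i for i in self.individuals if i not in self.pop_of]
        if missing_pop:
            raise SSRValidationError(f"individuals without population label: {missing_pop}")

        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise SSRValidationError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise SSRValidationError(
                f"half-missing call for sample {self.individuals[i]!r} "
                f"at locus {self.loci[j]!r}"
            )
        self.calls = np.sort(calls, axis=2)
        self.calls.setflags(write=False)

        # population order = first appearance over the individual order
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.pop_of[ind], None)
        self.populations: tuple[str, ...] = tuple(seen)

    # -- basic introspection -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(str(locus))
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def population_rows(self, population: str) -> np.ndarray:
        population = str(population)
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        return np.array(
            [k for k, ind in enumerate(self.individuals) if self.pop_of[ind] == population],
            dtype=np.intp,
        )

    def calls_at(self, population: str, locus: str) -> np.ndarray:
        """Non-missing genotype pairs for one population at one locus, shape (m, 2)."""
        rows = self.population_rows(population)
        block = self.calls[rows, self.locus_index(locus), :]
        return block[block[:, 0] != MISSING]

    def population_view(self, population: str) -> PopulationView:
        rows = self.population_rows(population)
        n_per = {
            loc: int((self.calls[rows, j, 0] != MISSING).sum())
            for j, loc in enumerate(self.loci)
        }
        return PopulationView(str(population), len(rows), n_per)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self.pop_of == other.pop_of
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_individuals} individuals, "
            f"{self.n_loci} loci, {len(self.populations)} populations)"
        )


# -- allele frequencies ------------------------------------------------------


def allele_frequencies(g: GenotypeMatrix, population: str, locus: str) -> dict[int, float]:
    """Sample allele frequencies for one population at one locus.

    Missing calls are excluded from both numerator and denominator, so
    the frequencies are counts over the ``2 * N_l`` observed gene copies
    and sum to 1.

    Raises
    ------
    NoDataError
        If the population has no non-missing call at the locus.
    """
    pairs = g.calls_at(population, locus)
    if pairs.shape[0] == 0:
        raise NoDataError(str(population), str(locus))
    alleles, counts = np.unique(pairs.ravel(), return_counts=True)
    total = counts.sum()
    return {int(a): float(c) / total for a, c in zip(alleles, counts)}


# -- GenAlEx-dialect CSV -----------------------------------------------------


def read_genalex(path) -> GenotypeMatrix:
    """Read a GenAlEx-dialect codominant CSV.

    Layout: row 1 holds ``n_loci, n_samples, n_pops, size_pop1, ...``;
    row 2 is free-form titles; row 3 names the columns (sample, pop,
    then two columns per locus, the locus name in the first of each
    pair); data rows follow with integer alleles, 0 or blank = missing.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh)]
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if len(rows) < 4:
        raise SSRFormatError("file too short: need 3 header rows plus data")

    header = rows[0]
    try:
        n_loci, n_samples, n_pops = (int(header[k]) for k in range(3))
        pop_sizes = [int(x) for x in header[3 : 3 + n_pops]]
    except (IndexError, ValueError):
        raise SSRFormatError(f"malformed count header (row 1): {header!r}") from None
    if len(pop_sizes) != n_pops:
        raise SSRFormatError(f"row 1 lists {len(pop_sizes)} population sizes, expected {n_pops}")
    if sum(pop_sizes) != n_samples:
        raise SSRFormatError(
            f"row 1: population sizes sum to {sum(pop_sizes)}, expected {n_samples} samples"
        )

    colnames = list(rows[2])
    expected_cols = 2 + 2 * n_loci
    # the second column of the last locus pair is blank and may be dropped
    # by CSV writers that trim trailing delimiters
    if len(colnames) == expected_cols - 1:
        colnames.append("")
    if len(colnames) < expected_cols:
        raise SSRFormatError(
            f"row 3 has {len(colnames)} columns, expected {expected_cols} "
            f"(sample, pop, two per locus)"
        )
    loci = []
    for j in range(n_loci):
        name = colnames[2 + 2 * j].strip()
        loci.append(name if name else f"Locus{j + 1}")

    data = rows[3:]
    if len(data) != n_samples:
        raise SSRFormatError(f"row 1 declares {n_samples} samples but body has {len(data)} rows")

    individuals: list[str] = []
    pop_of: dict[str, str] = {}
    calls = np.zeros((n_samples, n_loci, 2), dtype=np.int64)
    for i, row in enumerate(data):
        if (len(row) - 2) % 2 != 0:
            raise SSRFormatError(
                f"data row {i + 4} has an odd allele-column count ({len(row) - 2})"
            )
        if len(row) < expected_cols:
            raise SSRFormatError(
                f"data row {i + 4} has {len(row)} columns, expected {expected_cols}"
            )
        sample = row[0].strip()
        pop = row[1].strip()
        if not sample or not pop:
            raise SSRFormatError(f"data row {i + 4}: empty sample or population field")
        individuals.append(sample)
        pop_of[sample] = pop
        for j in range(n_loci):
            a = _normalize_allele(row[2 + 2 * j])
            b = _normalize_allele(row[3 + 2 * j])
            calls[i, j] = (a, b)

    g = GenotypeMatrix(individuals, loci, pop_of, calls)
    observed_sizes = [g.population_view(p).n_total for p in g.populations]
    if observed_sizes != pop_sizes:
        raise SSRFormatError(
            f"row 1 population sizes {pop_sizes} do not match body sizes {observed_sizes}"
        )
    return g


def write_genalex(g: GenotypeMatrix, path, title: str = "ssrpopgen export") -> None:
    """Write the GenAlEx-dialect CSV consumed by :func:`read_genalex`."""
    sizes = [g.population_view(p).n_total for p in g.populations]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([g.n_loci, g.n_individuals, len(g.populations), *sizes])
        w.writerow([title, "", *g.populations])
        row3: list[str] = ["Sample", "Pop"]
        for loc in g.loci:
            row3 += [loc, ""]
        w.writerow(row3)
        for i, ind in enumerate(g.individuals):
            row: list[object] = [ind, g.pop_of[ind]]
            for j in range(g.n_loci):
                row += [int(g.calls[i, j, 0]), int(g.calls[i, j, 1])]
            w.writerow(row)


# -- long-format TSV ---------------------------------------------------------

_LONG_COLS = ("sample", "population", "locus", "allele1", "allele2")


def read_long_tsv(path) -> GenotypeMatrix:
    """Read the long-format TSV (one row per sample × locus call).

    Columns: ``sample, population, locus, allele1, allele2``.  The
    resulting matrix is identical to an equivalent GenAlEx file; sample
    order and locus order follow first appearance.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in reader if any(cell.strip() for cell in r)]
    if not rows:
        raise SSRFormatError("no records")
    header = [c.strip().lower() for c in rows[0]]
    if tuple(header[:5]) != _LONG_COLS:
        raise SSRFormatError(f"expected columns {_LONG_COLS}, got {rows[0]!r}")
    body = rows[1:]
    if not body:
        raise SSRFormatError("no records")

    individuals: list[str] = []
    loci: list[str] = []
    pop_of: dict[str, str] = {}
    records: dict[tuple[str, str], tuple[int, int]] = {}
    for r, row in enumerate(body, start=2):
        if len(row) < 5:
            raise SSRFormatError(f"row {r}: expected 5 fields, got {len(row)}")
        sample, pop, locus = (row[k].strip() for k in range(3))
        key = (sample, locus)
        if key in records:
            raise SSRFormatError(f"row {r}: duplicate record for sample {sample!r}, locus {locus!r}")
        if sample not in pop_of:
            individuals.append(sample)
            pop_of[sample] = pop
        elif pop_of[sample] != pop:
            raise SSRValidationError(
                f"row {r}: sample {sample!r} assigned to two populations "
                f"({pop_of[sample]!r}, {pop!r})"
            )
        if locus not in loci:
            loci.append(locus)
        records[key] = (_normalize_allele(row[3]), _normalize_allele(row[4]))

    calls = np.zeros((len(individuals), len(loci), 2), dtype=np.int64)
    for (sample, locus), pair in records.items():
        calls[individuals.index(sample), loci.index(locus)] = pair
    return GenotypeMatrix(individuals, loci, pop_of, calls)


def write_long_tsv(g: GenotypeMatrix, path) -> None:
    """Write the long-format TSV consumed by :func:`read_long_tsv`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_LONG_COLS)
        for i, ind in enumerate(g.individuals):
            for j, loc in enumerate(g.loci):
                w.writerow([ind, g.pop_of[ind], loc, int(g.calls[i, j, 0]), int(g.calls[i, j, 1])])
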