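"""Diploid microsatellite genotypes and Genepop text I/O.

The :class:`GenotypeDataset` is the interchange currency of the whole
package: every estimator consumes one and every simulator can emit one.
Genotypes are stored per population as integer arrays of shape
``(n_individuals, n_loci, 2)`` whose entries are allele codes (allele
sizes in base pairs); ``0`` marks a missing allele call.

The Genepop dialect implemented here accepts both comma-separated and
one-locus-per-line headers, 2- and 3-digit allele encodings
(auto-detected), and the ``00``/``000`` missing-data convention.  Writing
always emits one locus name per line and is deterministic, so a
write→read round trip is the identity on allele content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
]

#: Sentinel allele code for a missing call.  Genepop encodes missing data
#: as all-zero fields, so 0 can never be a real allele size.
MISSING = 0


class GenepopParseError(ValueError):
    """Raised when a Genepop file cannot be parsed."""


@dataclass
class GenotypeDataset:
    """Diploid multi-locus genotypes grouped into populations.

    Parameters
    ----------
    loci
        Ordered locus names.
    genotypes
        Mapping population label -> int array ``(n_i, L, 2)``.  Allele
        codes are positive integers; ``MISSING`` (0) marks missing calls.
        Both entries of a call are either positive or both 0.
    individual_ids
        Optional mapping population label -> list of individual labels.
    """

    loci: list[str]
    genotypes: dict[str, np.ndarray]
    individual_ids: dict[str, list[str]] = field(default_factory=dict)
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        clean: dict[str, np.ndarray] = {}
        for pop, arr in self.genotypes.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 3 or arr.shape[1] != len(self.loci) or arr.shape[2] != 2:
                raise ValueError(
                    f"population {pop!r}: genotype array must have shape "
                    f"(n, {len(self.loci)}, 2), got {arr.shape}"
                )
            if (arr < 0).any():
                raise ValueError(f"population {pop!r}: negative allele code")
            # a call is missing as a unit, not one allele at a time
            half = (arr == MISSING).sum(axis=2)
            if np.any(half == 1):
                raise ValueError(f"population {pop!r}: half-missing genotype call")
            clean[pop] = arr
        self.genotypes = clean
        for pop in self.genotypes:
            ids = self.individual_ids.get(pop)
            if ids is None:
                self.individual_ids[pop] = [
                    f"{pop}_{i + 1}" for i in range(len(self.genotypes[pop]))
                ]
            elif len(ids) != len(self.genotypes[pop]):
                raise ValueError(f"population {pop!r}: id/genotype length mismatch")

    # ------------------------------------------------------------------
    @property
    def populations(self) -> list[str]:
        return list(self.genotypes)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def n_individuals(self, population: str | None = None) -> int:
        if population is not None:
            return len(self._pop(population))
        return sum(len(a) for a in self.genotypes.values())

    def _pop(self, population: str) -> np.ndarray:
        try:
            return self.genotypes[population]
        except KeyError:
            raise KeyError(f"unknown population {population!r}") from None

    def _locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def locus_calls(self, locus: str, population: str) -> np.ndarray:
        """Non-missing diploid calls ``(m, 2)`` at one locus in one population."""
        arr = self._pop(population)[:, self._locus_index(locus), :]
        return arr[arr[:, 0] != MISSING]

    def allele_counts(self, locus: str, population: str) -> dict[int, int]:
        """Gene-copy counts per allele; missing calls contribute nothing."""
        calls = self.locus_calls(locus, population)
        alleles, counts = np.unique(calls.ravel(), return_counts=True)
        return {int(a): int(c) for a, c in zip(alleles, counts)}

    def observed_alleles(self, locus: str | None = None) -> set[int]:
        """All allele codes seen at one locus (or anywhere) across populations."""
        out: set[int] = set()
        for pop in self.populations:
            arr = self._pop(pop)
            if locus is None:
                vals = arr.ravel()
            else:
                vals = arr[:, self._locus_index(locus), :].ravel()
            out.update(int(v) for v in np.unique(vals) if v != MISSING)
        return out

    def subset(self, populations: Sequence[str]) -> "GenotypeDataset":
        return GenotypeDataset(
            loci=self.loci,
            genotypes={p: self._pop(p).copy() for p in populations},
            individual_ids={p: list(self.individual_ids[p]) for p in populations},
        )

    def to_frequencies(self) -> "AlleleFrequencyTable":
        """Per population × locus sample allele frequencies."""
        if not self.populations or not self.loci:
            raise ValueError("empty dataset")
        counts: dict[str, dict[str, dict[int, int]]] = {}
        for pop in self.populations:
            counts[pop] = {
                locus: self.allele_counts(locus, pop) for locus in self.loci
            }
        return AlleleFrequencyTable.from_counts(self.loci, counts)

    def max_allele(self) -> int:
        return max((int(a.max()) for a in self.genotypes.values() if a.size), default=0)


@dataclass
class AlleleFrequencyTable:
    """Per population × locus allele frequencies with gene-copy counts.

    ``freqs[pop][locus]`` maps allele code -> relative frequency;
    ``n[pop][locus]`` is the number of gene copies the frequencies were
    estimated from (0 flags an empty cell).
    """

    loci: list[str]
    freqs: dict[str, dict[str, dict[int, float]]]
    n: dict[str, dict[str, int]]

    @classmethod
    def from_counts(
        cls, loci: Sequence[str], counts: Mapping[str, Mapping[str, Mapping[int, int]]]
    ) -> "AlleleFrequencyTable":
        freqs: dict[str, dict[str, dict[int, float]]] = {}
        n: dict[str, dict[str, int]] = {}
        for pop, bylocus in counts.items():
            freqs[pop] = {}
            n[pop] = {}
            for locus in loci:
                c = dict(bylocus.get(locus, {}))
                tot = sum(c.values())
                n[pop][locus] = int(tot)
                freqs[pop][locus] = (
                    {int(a): c[a] / tot for a in sorted(c)} if tot else {}
                )
        return cls(loci=list(loci), freqs=freqs, n=n)

    @classmethod
    def single_pool(
        cls, loci: Sequence[str], freqs: Mapping[str, Mapping[int, float]],
        label: str = "pool", n: int | Mapping[str, int] = 0,
    ) -> "AlleleFrequencyTable":
        """Build a one-population table (a simulation baseline)."""
        by_locus = {}
        n_map = {}
        for locus in loci:
            f = dict(freqs[locus])
            tot = sum(f.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"locus {locus!r}: frequencies sum to {tot}")
            by_locus[locus] = {int(a): float(f[a]) for a in sorted(f)}
            n_map[locus] = n if isinstance(n, int) else int(n[locus])
        return cls(loci=list(loci), freqs={label: by_locus}, n={label: n_map})

    @property
    def populations(self) -> list[str]:
        return list(self.freqs)

    def cell(self, population: str, locus: str) -> dict[int, float]:
        return self.freqs[population][locus]

    def locus_vectors(self, locus: str) -> tuple[np.ndarray, np.ndarray]:
        """Union allele list and a (pops × alleles) frequency matrix."""
        alleles = sorted({a for p in self.populations for a in self.freqs[p][locus]})
        mat = np.zeros((len(self.populations), len(alleles)))
        for i, pop in enumerate(self.populations):
            cell = self.freqs[pop][locus]
            for j, a in enumerate(alleles):
                mat[i, j] = cell.get(a, 0.0)
        return np.asarray(alleles), mat

    def validate(self) -> None:
        for pop in self.populations:
            for locus in self.loci:
                cell = self.freqs[pop][locus]
                if not cell:
                    continue
                vals = np.array(list(cell.values()))
                if (vals < 0).any() or (vals > 1).any():
                    raise ValueError(f"{pop}/{locus}: frequency outside [0,1]")
                if abs(vals.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{pop}/{locus}: frequencies sum to {vals.sum()}")


# ----------------------------------------------------------------------
# Genepop text format
# ----------------------------------------------------------------------

def _detect_digits(fields: Iterable[str]) -> int:
    for f in fields:
        if len(f) in (4, 6):
            return len(f) // 2
    raise GenepopParseError("cannot detect allele encoding width")


def read_genepop(path: str | Path) -> GenotypeDataset:
    """Read a Genepop file into a :class:`GenotypeDataset`.

    Population labels are taken from the identifier of the last
    individual of each POP block (the usual Genepop convention); if the
    same label recurs, a ``pop_k`` fallback keeps labels unique.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GenepopParseError(f"{path}: empty file")
    # header/title line is free text and skipped
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and not (
        body[i].strip().upper() == "POP"
        or body[i].strip().upper().startswith("POP ")
    ):
        chunk = body[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenepopParseError(f"{path}: no loci before first POP line")
    if i >= len(body):
        raise GenepopParseError(f"{path}: no POP block")

    blocks: list[tuple[str | None, list[tuple[str, list[str]]]]] = []
    digits: int | None = None
    for lineno, raw in enumerate(body[i:], start=i + 2):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP" or line.upper().startswith("POP "):
            # an explicit label may trail the POP keyword
            blocks.append((line[3:].strip() or None, []))
            continue
        if not blocks:
            raise GenepopParseError(f"{path}:{lineno}: individual before POP line")
        if "," not in line:
            raise GenepopParseError(f"{path}:{lineno}: expected 'id , genotypes'")
        ident, geno = line.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise GenepopParseError(
                f"{path}:{lineno}: {len(fields)} genotype fields for {len(loci)} loci"
            )
        for f in fields:
            if len(f) not in (4, 6):
                raise GenepopParseError(
                    f"{path}:{lineno}: malformed genotype field {f!r}"
                )
        if digits is None:
            digits = _detect_digits(fields)
        blocks[-1][1].append((ident.strip(), fields))
    blocks = [b for b in blocks if b[1]]
    if not blocks:
        raise GenepopParseError(f"{path}: no individuals")
    assert digits is not None

    genotypes: dict[str, np.ndarray] = {}
    ids: dict[str, list[str]] = {}
    for k, (given, block) in enumerate(blocks):
        label = given or block[-1][0] or f"pop_{k + 1}"
        if label in genotypes:
            label = f"pop_{k + 1}"
        arr = np.zeros((len(block), len(loci), 2), dtype=np.int64)
        for r, (_, fields) in enumerate(block):
            for c, f in enumerate(fields):
                a1, a2 = int(f[:digits]), int(f[digits:])
                if (a1 == 0) != (a2 == 0):
                    a1 = a2 = MISSING  # half-missing treated as missing call
                arr[r, c, 0], arr[r, c, 1] = a1, a2
        genotypes[label] = arr
        ids[label] = [ident for ident, _ in block]
    return GenotypeDataset(loci=loci, genotypes=genotypes, individual_ids=ids)


def write_genepop(
    ds: GenotypeDataset,
    path: str | Path,
    digits: int | None = None,
    title: str = "msatpop export",
) -> Path:
    """Write a dataset in Genepop format (one locus name per line).

    ``digits`` defaults to the smallest width (2 or 3) that fits every
    allele code in the dataset.
    """
    if not ds.populations:
        raise ValueError("dataset has no populations")
    if not ds.loci:
        raise ValueError("dataset has no loci")
    biggest = ds.max_allele()
    if digits is None:
        digits = 2 if biggest < 100 else 3
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    if biggest >= 10 ** digits:
        raise ValueError(
            f"allele code {biggest} does not fit in {digits}-digit encoding"
        )
    path = Path(path)
    out = [title]
    out.extend(ds.loci)
    for pop in ds.populations:
        out.append("POP")
        arr = ds.genotypes[pop]
        for r in range(len(arr)):
            fields = [
                f"{arr[r, c, 0]:0{digits}d}{arr[r, c, 1]:0{digits}d}"
                for c in range(len(ds.loci))
            ]
            out.append(f"{ds.individual_ids[pop][r]} ,  " + " ".join(fields))
    path.write_text("\n".join(out) + "\n")
    return path


def allele_counts(ds: GenotypeDataset, locus: str, population: str) -> dict[int, int]:
    """Functional alias for :meth:`GenotypeDataset.allele_counts`."""
    return ds.allele_counts(locus, population)


def to_frequencies(ds: GenotypeDataset) -> AlleleFrequencyTable:
    """Functional alias for :meth:`GenotypeDataset.to_frequencies`."""
    return ds.to_frequencies()
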