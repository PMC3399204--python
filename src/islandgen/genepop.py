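"""GenePop-dialect text I/O for diploid microsatellite genotypes.

Dialect accepted: a title line; one locus name per line (or a single
comma-separated line); ``POP``/``Pop``/``pop`` separators; individual rows
``id , a1a1 a2a2 ...`` with 2- or 3-digit allele encoding (auto-detected);
``00``/``000`` encodes a missing gene.  Written files use 3-digit encoding by
default and one locus name per line.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .core import MISSING, GenotypeMatrix

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


class GenePopParseError(ValueError):
    """Malformed GenePop input, with the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _split_genotype(token: str, line_no: int) -> tuple[int, int]:
    if len(token) == 4:
        w = 2
    elif len(token) == 6:
        w = 3
    else:
        raise GenePopParseError(
            f"genotype token {token!r} is not 4 or 6 digits", line_no
        )
    if not token.isdigit():
        raise GenePopParseError(f"non-numeric genotype token {token!r}", line_no)
    a, b = int(token[:w]), int(token[w:])
    if (a == 0) != (b == 0):
        raise GenePopParseError(
            f"half-missing genotype token {token!r}", line_no
        )
    return a, b


def read_genepop(path: str | Path, population_names: list[str] | None = None) -> GenotypeMatrix:
    """Parse a GenePop file into a :class:`GenotypeMatrix`.

    Populations appear in file order and are named ``pop1``..``popK`` (or the
    last individual id of each block is NOT used, deliberately: block-position
    names are stable under re-sampling).  ``population_names`` overrides the
    generated labels.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenePopParseError("file too short to be GenePop")
    # locus names: lines 2..first POP; a single comma-separated line also legal
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        part = lines[i].strip()
        if part:
            if "," in part:
                loci.extend(t.strip() for t in part.split(",") if t.strip())
            else:
                loci.append(part)
        i += 1
    if i == len(lines):
        raise GenePopParseError("no POP separator found")
    if not loci:
        raise GenePopParseError("no locus names before first POP")

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_no = 0
    block_size = 0
    while i < len(lines):
        if _POP_RE.match(lines[i]):
            if pop_no > 0 and block_size == 0:
                raise GenePopParseError("empty POP block", i)
            pop_no += 1
            block_size = 0
            i += 1
            continue
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if "," not in line:
            raise GenePopParseError("individual row lacks ',' separator", i + 1)
        ind, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenePopParseError(
                f"expected {len(loci)} genotypes, found {len(tokens)}", i + 1
            )
        rows.append([_split_genotype(t, i + 1) for t in tokens])
        individuals.append(ind.strip())
        populations.append(f"pop{pop_no}")
        block_size += 1
        i += 1
    if pop_no == 0:
        raise GenePopParseError("no POP separator found")
    if block_size == 0:
        raise GenePopParseError("empty POP block", len(lines))

    if population_names is not None:
        if len(population_names) != pop_no:
            raise GenePopParseError(
                f"{len(population_names)} population names for {pop_no} blocks"
            )
        rename = {f"pop{k + 1}": population_names[k] for k in range(pop_no)}
        populations = [rename[p] for p in populations]

    calls = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(individuals, loci, populations, calls)


def write_genepop(
    gm: GenotypeMatrix,
    path: str | Path,
    title: str = "islandgen genotypes",
    digits: int = 3,
) -> None:
    """Write a GenotypeMatrix as GenePop text (3-digit encoding by default)."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10**digits - 1
    if int(gm.calls.max(initial=0)) > limit:
        raise ValueError(
            f"allele label {int(gm.calls.max())} exceeds {digits}-digit encoding"
        )
    out = [title]
    out.extend(gm.loci)
    current_pop: str | None = None
    for i, ind in enumerate(gm.individuals):
        if gm.populations[i] != current_pop:
            out.append("POP")
            current_pop = gm.populations[i]
        tokens = [
            f"{a:0{digits}d}{b:0{digits}d}" for a, b in gm.calls[i]
        ]
        out.append(f"{ind} , " + " ".join(tokens))
    Path(path).write_text("\n".join(out) + "\n")


def genotypes_equal(a: GenotypeMatrix, b: GenotypeMatrix) -> bool:
    """Equality up to within-genotype allele order and population renaming."""
    if a.individuals != b.individuals or a.loci != b.loci:
        return False
    if [a.populations.index(p) for p in a.populations] != [
        b.populations.index(p) for p in b.populations
    ]:
        return False
    return bool(
        np.array_equal(np.sort(a.calls, axis=2), np.sort(b.calls, axis=2))
    )
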