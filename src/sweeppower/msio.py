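"""Hudson ``ms``-format text I/O.

The exchange dialect: a command-echo line, a seeds line, then blank-line
separated replicates, each ``//`` + ``segsites: S`` + ``positions: ...``
(fractions of the region length, 5 decimal places) + one 0/1 string per
chromosome.  A replicate with ``segsites: 0`` has no positions line.
Positions are stored internally in base pairs and rescaled only here.
"""

from __future__ import annotations

from typing import Iterable, Sequence, TextIO

import numpy as np

from .simulate import HaplotypeMatrix

__all__ = ["write_ms", "read_ms"]


def write_ms(
    replicates: Sequence[HaplotypeMatrix],
    stream: TextIO,
    header: str = "sweeppower",
    seeds: Iterable[int] = (0, 0, 0),
) -> None:
    """Write replicates as an ``ms``-format stream."""
    if not replicates:
        raise ValueError("no replicates to write")
    n0 = replicates[0].n
    L0 = replicates[0].L
    for h in replicates:
        if h.n != n0 or h.L != L0:
            raise ValueError("all replicates must share n and L")
    stream.write(f"{header}\n")
    stream.write(" ".join(str(s) for s in seeds) + "\n")
    for h in replicates:
        stream.write("\n//\n")
        stream.write(f"segsites: {h.S}\n")
        if h.S:
            fracs = " ".join(f"{p / h.L:.5f}" for p in h.positions)
            stream.write(f"positions: {fracs}\n")
            for row in h.alleles:
                stream.write("".join("1" if a else "0" for a in row) + "\n")


def read_ms(stream: TextIO, L: float) -> list[HaplotypeMatrix]:
    """Parse an ``ms``-format stream; positions are rescaled to base pairs."""
    lines = stream.read().splitlines()
    out: list[HaplotypeMatrix] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        if i >= n_lines or not lines[i].startswith("segsites:"):
            raise ValueError(f"line {i + 1}: expected 'segsites:' after '//'")
        try:
            S = int(lines[i].split(":", 1)[1])
        except ValueError:
            raise ValueError(f"line {i + 1}: malformed segsites value") from None
        i += 1
        if S == 0:
            out.append(HaplotypeMatrix(np.zeros((0, 0), dtype=np.uint8),
                                       np.zeros(0), L))
            continue
        if i >= n_lines or not lines[i].startswith("positions:"):
            raise ValueError(f"line {i + 1}: expected 'positions:' line")
        fracs = lines[i].split(":", 1)[1].split()
        if len(fracs) != S:
            raise ValueError(
                f"line {i + 1}: {len(fracs)} positions for segsites: {S}"
            )
        positions = np.array([float(x) for x in fracs]) * L
        # guard against ties introduced by the 5-decimal formatting
        for j in range(1, S):
            if positions[j] <= positions[j - 1]:
                positions[j] = np.nextafter(positions[j - 1], np.inf)
        i += 1
        rows = []
        while i < n_lines and lines[i].strip() and lines[i].strip() != "//":
            text = lines[i].strip()
            if set(text) - {"0", "1"}:
                raise ValueError(f"line {i + 1}: non-binary haplotype characters")
            if len(text) != S:
                raise ValueError(
                    f"line {i + 1}: haplotype length {len(text)} != segsites {S}"
                )
            rows.append([int(c) for c in text])
            i += 1
        if not rows:
            raise ValueError(f"line {i + 1}: replicate has no haplotype rows")
        out.append(HaplotypeMatrix(np.array(rows, dtype=np.uint8), positions, L))
    if not out:
        raise ValueError("no replicates found in stream")
    n0 = out[0].n
    for h in out:
        if h.n and h.n != n0:
            raise ValueError("inconsistent sample size across replicates")
    return out
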