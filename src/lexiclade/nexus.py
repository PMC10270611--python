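"""Minimal extended-NEXUS reader/writer for binary matrices and split systems.

Covers the dialect this package exchanges with phylogenetic inference and
split-network viewers: a DATA block with symbols "01" and missing "?", a SETS
block with one CHARSET per partition, an ASSUMPTIONS-style TIPAGES comment
block, and a SPLITS block (TAXLABELS, CYCLE, MATRIX) for weighted circular
split systems.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .wordlist import ABSENT, MISSING, PRESENT, BinaryMatrix

_SYM = {PRESENT: "1", ABSENT: "0", MISSING: "?"}
_VAL = {"1": PRESENT, "0": ABSENT, "?": MISSING}


def _quote(label: str) -> str:
    return f"'{label}'" if re.search(r"[\s(){}\[\]/\\,;:=*'\"`+<>-]", label) else label


def write_nexus(m: BinaryMatrix, path) -> None:
    """Write a BinaryMatrix as extended NEXUS (DATA + SETS + tip ages)."""
    lines = ["#NEXUS", ""]
    lines.append("BEGIN DATA;")
    lines.append(f"  DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_chars};")
    lines.append('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;')
    lines.append("  MATRIX")
    width = max((len(t) for t in m.taxa), default=1) + 2
    for i, t in enumerate(m.taxa):
        row = "".join(_SYM[int(v)] for v in m.cells[i])
        lines.append(f"    {_quote(t):<{width}} {row}")
    lines.append("  ;")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN SETS;")
    for label in m.partition_labels():
        cols = m.partition_columns(label) + 1  # NEXUS is 1-based
        spans = _ranges(sorted(cols))
        span_s = " ".join(f"{a}-{b}" if a != b else f"{a}" for a, b in spans)
        lines.append(f"  CHARSET {label} = {span_s};")
    lines.append("END;")
    lines.append("")
    # per-taxon tip-age annotations (years BP), read back by this package
    lines.append("[TIPAGES")
    for t in m.taxa:
        lines.append(f"  {_quote(t)} = {m.tip_ages.get(t, 0.0):g}")
    lines.append("]")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _ranges(cols) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for c in cols:
        if out and c == out[-1][1] + 1:
            out[-1] = (out[-1][0], c)
        else:
            out.append((c, c))
    return out


def _tokens_in_block(text: str, block: str) -> str:
    mm = re.search(rf"BEGIN\s+{block}\s*;(.*?)END\s*;", text, re.S | re.I)
    if not mm:
        raise ValueError(f"no {block} block found")
    return mm.group(1)


def read_nexus(path) -> BinaryMatrix:
    """Read a BinaryMatrix written by :func:`write_nexus` (round-trip)."""
    text = Path(path).read_text(encoding="utf-8")
    tipages: dict[str, float] = {}
    mt = re.search(r"\[TIPAGES(.*?)\]", text, re.S)
    if mt:
        for line in mt.group(1).strip().splitlines():
            name, _, val = line.partition("=")
            tipages[name.strip().strip("'")] = float(val)
    text_nc = re.sub(r"\[.*?\]", "", text, flags=re.S)

    data = _tokens_in_block(text_nc, "DATA")
    mmat = re.search(r"MATRIX(.*?);", data, re.S | re.I)
    if not mmat:
        raise ValueError("no MATRIX in DATA block")
    taxa: list[str] = []
    rows: list[list[int]] = []
    for line in mmat.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            name, rest = re.match(r"'([^']*)'\s*(.*)", line).groups()
        else:
            name, _, rest = line.partition(" ")
        taxa.append(name)
        rows.append([_VAL[ch] for ch in rest.strip()])
    cells = np.array(rows, dtype=np.int8)

    partitions = ["all"] * cells.shape[1]
    try:
        sets = _tokens_in_block(text_nc, "SETS")
        for name, spans in re.findall(r"CHARSET\s+(\S+)\s*=\s*([^;]+);", sets, re.I):
            for tok in spans.split():
                if "-" in tok:
                    a, b = tok.split("-")
                    for j in range(int(a) - 1, int(b)):
                        partitions[j] = name
                else:
                    partitions[int(tok) - 1] = name
    except ValueError:
        pass

    chars = list(range(1, cells.shape[1] + 1))
    return BinaryMatrix(taxa, chars, ["?"] * len(chars), cells, partitions, tipages)


# ---------------------------------------------------------------------------
# SPLITS block


def write_splits_nexus(s, path) -> None:
    """Write a SplitSystem as a NEXUS SPLITS block readable by network viewers."""
    n = len(s.taxa)
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"  DIMENSIONS NTAX={n};", "  TAXLABELS"]
    for t in s.taxa:
        lines.append(f"    {_quote(t)}")
    lines += ["  ;", "END;", "", "BEGIN SPLITS;"]
    lines.append(f"  DIMENSIONS NTAX={n} NSPLITS={len(s.splits)};")
    lines.append("  FORMAT LABELS=NO WEIGHTS=YES;")
    cycle = " ".join(str(i + 1) for i in s.ordering)
    lines.append(f"  CYCLE {cycle};")
    lines.append("  MATRIX")
    for side, w in s.splits:
        members = " ".join(str(i + 1) for i in sorted(side))
        lines.append(f"    {w:.10g}  {members},")
    lines += ["  ;", "END;"]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_splits_nexus(path):
    """Read back a SPLITS file written by :func:`write_splits_nexus`."""
    from .splits import SplitSystem

    text = Path(path).read_text(encoding="utf-8")
    taxa_block = _tokens_in_block(text, "TAXA")
    mlab = re.search(r"TAXLABELS(.*?);", taxa_block, re.S | re.I)
    taxa = [t.strip().strip("'") for t in mlab.group(1).split("\n") if t.strip()]
    sp = _tokens_in_block(text, "SPLITS")
    cyc = re.search(r"CYCLE\s+([^;]+);", sp, re.I)
    ordering = [int(x) - 1 for x in cyc.group(1).split()]
    splits: list[tuple[frozenset, float]] = []
    mmat = re.search(r"MATRIX(.*?);", sp, re.S | re.I)
    body = mmat.group(1)
    for line in body.strip().splitlines():
        line = line.strip().rstrip(",")
        if not line:
            continue
        parts = line.split()
        w = float(parts[0])
        side = frozenset(int(x) - 1 for x in parts[1:])
        splits.append((side, w))
    return SplitSystem(taxa, ordering, splits)
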