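"""Serialization of interactions: tab-delimited tables, summaries, and
RasMol/Jmol selection scripts.

Tables carry a ``#``-prefixed provenance block (input id, atom type, window,
sequence-separation, selection), one row per interaction, member descriptors
as ``CHAIN:RESNAME:RESNUM[:ICODE]`` and distances printed to a fixed number
of decimals (2 by default, matching how such distances are conventionally
reported).  Identical inputs and configuration produce byte-identical files.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .cliques import Interaction, ResidueKey
from .errors import RescliqueError
from .structure_io import Site

_DIALECTS = ("rasmol", "jmol")

#: color per interaction order in visualization scripts
ORDER_COLORS = {2: "yellow", 3: "orange", 4: "red"}


def _member_descriptor(site: Site) -> str:
    return site.label()


def parse_member_descriptor(text: str) -> tuple[ResidueKey, str]:
    """Invert :func:`_member_descriptor`: returns (residue_key, aa_type)."""
    parts = text.split(":")
    if len(parts) not in (3, 4):
        raise RescliqueError(f"cannot parse member descriptor {text!r}")
    chain, aa, num = parts[0], parts[1], int(parts[2])
    icode = parts[3] if len(parts) == 4 else None
    return ((chain, num, icode), aa)


def _columns(order: int) -> list[str]:
    cols = ["order"]
    cols += [f"member{m}" for m in range(1, order + 1)]
    cols += [f"d_{a}_{b}" for a, b in combinations(range(1, order + 1), 2)]
    cols.append("span")
    return cols


def _row(it: Interaction, order: int, precision: int) -> list[str]:
    # place every value under its named column so mixed-order tables align
    values = {"order": str(it.order), "span": it.span}
    for m, site in enumerate(it.members, start=1):
        values[f"member{m}"] = _member_descriptor(site)
    for a, b in combinations(range(it.order), 2):
        values[f"d_{a + 1}_{b + 1}"] = f"{it.distance(a, b):.{precision}f}"
    return [values.get(col, "") for col in _columns(order)]


def write_interactions_tsv(
    interactions: Sequence[Interaction],
    destination: Union[str, IO[str]],
    provenance: Optional[Mapping[str, object]] = None,
    precision: int = 2,
) -> None:
    """Write interactions as UTF-8 TSV with a ``#`` provenance header.

    A mixed-order list is padded to the widest order's column layout (blank
    fields); a homogeneous list gets exactly its order's columns.
    """
    interactions = list(interactions)
    width = max((it.order for it in interactions), default=2)
    cols = _columns(width)

    lines: list[str] = []
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}: {value}")
    lines.append("\t".join(cols))
    for it in interactions:
        lines.append("\t".join(_row(it, width, precision)))
    text = "\n".join(lines) + "\n"

    if isinstance(destination, str):
        with open(destination, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    else:
        destination.write(text)


@dataclass(frozen=True)
class TableRow:
    order: int
    member_keys: tuple[ResidueKey, ...]
    aa_types: tuple[str, ...]
    distances: tuple[float, ...]  # pair order: combinations of member positions
    span: str


def read_interactions_tsv(source: Union[str, IO[str]]) -> list[TableRow]:
    """Parse a table written by :func:`write_interactions_tsv` (round-trip)."""
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str, keep_default_na=False)
    rows: list[TableRow] = []
    for _, rec in df.iterrows():
        order = int(rec["order"])
        members = [
            parse_member_descriptor(rec[f"member{m}"]) for m in range(1, order + 1)
        ]
        dists = tuple(
            float(rec[f"d_{a}_{b}"])
            for a, b in combinations(range(1, order + 1), 2)
        )
        rows.append(
            TableRow(
                order=order,
                member_keys=tuple(k for k, _ in members),
                aa_types=tuple(aa for _, aa in members),
                distances=dists,
                span=rec["span"],
            )
        )
    return rows


# ---------------------------------------------------------------------------
# visualization scripts


def _rasmol_selector(site: Site) -> str:
    icode = site.icode or ""
    return f"{site.number}{icode}:{site.chain_id}"


def _jmol_selector(site: Site) -> str:
    icode = f"^{site.icode}" if site.icode else ""
    return f"{site.number}{icode}:{site.chain_id}"


def write_viz_script(
    interactions: Sequence[Interaction],
    dialect: str,
    destination: Union[str, IO[str]],
) -> None:
    """Emit a RasMol or Jmol script selecting and coloring each interaction.

    Each interaction becomes a selection of its member residues (by author
    number and chain) colored by order: pairs yellow, triplets orange,
    quadruplets red.
    """
    if dialect not in _DIALECTS:
        raise RescliqueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if not interactions:
        raise RescliqueError("no interactions to visualize")

    sel = _rasmol_selector if dialect == "rasmol" else _jmol_selector
    lines = ["# interaction highlight script", "wireframe off", "backbone 50"]
    for it in interactions:
        members = ", ".join(sel(s) for s in it.members)
        color = ORDER_COLORS[it.order]
        if dialect == "rasmol":
            lines += [f"select {members}", f"colour {color}", "spacefill 120"]
        else:
            lines += [f"select {members};", f"color {color};", "spacefill 0.5;"]
    text = "\n".join(lines) + "\n"

    if isinstance(destination, str):
        with open(destination, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    else:
        destination.write(text)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class Summary:
    """Counts per order, span breakdown, and per-residue participation.

    Invariant: summing participation at order k over all residues gives
    k × (number of order-k interactions).
    """

    counts: dict[int, int] = field(default_factory=dict)
    span_counts: dict[tuple[int, str], int] = field(default_factory=dict)
    participation: dict[ResidueKey, dict[int, int]] = field(default_factory=dict)


def summarize(
    interactions: Iterable[Interaction], sites: Sequence[Site]
) -> Summary:
    counts: Counter = Counter()
    span_counts: Counter = Counter()
    participation: dict[ResidueKey, dict[int, int]] = {
        s.residue_key: {} for s in sites
    }
    for it in interactions:
        counts[it.order] += 1
        span_counts[(it.order, it.span)] += 1
        for s in it.members:
            per = participation.setdefault(s.residue_key, {})
            per[it.order] = per.get(it.order, 0) + 1
    return Summary(
        counts=dict(counts),
        span_counts=dict(span_counts),
        participation=participation,
    )


def write_summary_tsv(summary: Summary, destination: Union[str, IO[str]]) -> None:
    lines = ["section\tkey\tvalue"]
    for order in sorted(summary.counts):
        lines.append(f"count\torder={order}\t{summary.counts[order]}")
    for (order, span) in sorted(summary.span_counts):
        lines.append(f"span\torder={order},{span}\t{summary.span_counts[(order, span)]}")
    for key in sorted(summary.participation, key=lambda k: (k[0], k[1], k[2] or "")):
        per = summary.participation[key]
        chain, num, icode = key
        label = f"{chain}:{num}{icode or ''}"
        joined = ",".join(f"{k}:{per[k]}" for k in sorted(per)) or "-"
        lines.append(f"participation\t{label}\t{joined}")
    text = "\n".join(lines) + "\n"
    if isinstance(destination, str):
        with open(destination, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    else:
        destination.write(text)
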