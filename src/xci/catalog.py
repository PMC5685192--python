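"""Harmonization of prior XCI-status catalogues.

Two expression-based surveys (somatic-cell-hybrid and allelic-imbalance
based) each assign X-linked genes one of three statuses: escape, variable
(escape in some lines/individuals) or inactive. This module merges such
catalogues into a single combined reference using explicit conflict rules:
a gene called escape in one study and variable in the other is escape;
escape vs inactive is variable; inactive vs variable is inactive; a gene
unique to one study keeps its original status.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

STATUSES = ("escape", "variable", "inactive")
ABSENT = "absent"


@dataclass(frozen=True)
class XiLineCount:
    """Number of Xi-carrying cell lines expressing a gene from Xi."""

    n_expressing_lines: int
    n_lines: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_expressing_lines <= self.n_lines):
            raise ValueError("need 0 <= n_expressing_lines <= n_lines")


def categorize_from_xi_counts(
    counts: XiLineCount, thresholds: tuple[float, float] = (2 / 9, 7 / 9)
) -> str:
    """Three-way status from the fraction of Xi hybrids expressing the gene.

    fraction < t_lo -> inactive; fraction >= t_hi -> escape; else variable.
    The default thresholds (2/9, 7/9) keep all three classes realizable on
    a nine-hybrid panel; both are configuration, not biology.
    """
    t_lo, t_hi = thresholds
    if not (0 <= t_lo < t_hi <= 1):
        raise ValueError(f"need 0 <= t_lo < t_hi <= 1, got {thresholds}")
    frac = counts.n_expressing_lines / counts.n_lines
    if frac < t_lo:
        return "inactive"
    if frac >= t_hi:
        return "escape"
    return "variable"


def harmonize_status(status_a: str, status_b: str) -> str:
    """Combine two per-study statuses into one, symmetrically.

    Equal statuses (or one study absent) pass through; conflicts resolve as
    escape+variable -> escape, escape+inactive -> variable,
    inactive+variable -> inactive.
    """
    valid = set(STATUSES) | {ABSENT}
    for s in (status_a, status_b):
        if s not in valid:
            raise ValueError(f"unknown status {s!r}")
    if status_a == ABSENT and status_b == ABSENT:
        raise ValueError("both statuses absent")
    if status_a == ABSENT:
        return status_b
    if status_b == ABSENT:
        return status_a
    if status_a == status_b:
        return status_a
    pair = frozenset((status_a, status_b))
    if pair == frozenset(("escape", "variable")):
        return "escape"
    if pair == frozenset(("escape", "inactive")):
        return "variable"
    if pair == frozenset(("inactive", "variable")):
        return "inactive"
    raise AssertionError(f"unhandled pair {pair}")  # pragma: no cover


def combine_catalogues(
    list_a: pd.DataFrame, list_b: pd.DataFrame, alias_map: dict[str, str] | None = None
) -> tuple[pd.DataFrame, Counter]:
    """Merge two catalogue tables (gene_id, gene_name, status, source) into
    one combined list over the union of genes, plus per-status counts.

    ``alias_map`` optionally maps alternative gene identifiers onto stable
    ones before matching; aliases that collide with an existing gene_id in
    the same list raise rather than silently merging.
    """
    frames = []
    for name, df in (("A", list_a), ("B", list_b)):
        df = df.copy()
        if alias_map:
            df["gene_id"] = df["gene_id"].map(lambda g: alias_map.get(g, g))
        dup = df["gene_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate gene_id in list {name}: {sorted(df.loc[dup, 'gene_id'])[:5]}"
            )
        frames.append(df.set_index("gene_id"))
    a, b = frames
    genes = a.index.union(b.index)
    rows = []
    for gene in genes:
        sa = a.loc[gene, "status"] if gene in a.index else ABSENT
        sb = b.loc[gene, "status"] if gene in b.index else ABSENT
        combined = harmonize_status(sa, sb)
        src = a if gene in a.index else b
        sources = [
            df.loc[gene, "source"] for df in (a, b) if gene in df.index
        ]
        rows.append(
            {
                "gene_id": gene,
                "gene_name": src.loc[gene, "gene_name"],
                "status": combined,
                "source": "+".join(str(s) for s in sources),
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "gene_name", "status", "source"])
    counts = Counter(out["status"])
    return out, counts
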