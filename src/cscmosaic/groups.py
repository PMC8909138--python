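"""Calling the cell populations and quantifying their overlap.

Seven populations are compared: slow-cycling cells (top 2% by lipid
score), fast-cycling cells (top 2% by CCS), and five marker-high groups
(CD133, SOX2, PTPRZ1, ITGB8, CD44).  Group homogeneity is screened with
the max/min-ratio (MMR) box-plot rule; the overlap structure (pairwise
intersections, private cells, multi-marker Combo_CSC membership) is exact
set arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
import numpy as np

from .io import ExpressionMatrix, ValidationError
from .scoring import CellScores


@dataclass
class CellGroup:
    """A named set of cells with the score that ranked them in.

    ``selector`` records how the group was called: ``kind`` is one of
    ``signature`` (enrichment score), ``cycle`` (cell-cycle score) or
    ``marker`` (single-gene expression), ``source`` names the score or
    gene, ``fraction`` the top fraction used.
    """

    name: str
    cell_ids: list[str]
    ranking_score: np.ndarray
    selector: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ranking_score = np.asarray(self.ranking_score, dtype=float)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError(f"group {self.name!r} has duplicate members")
        if self.ranking_score.shape != (len(self.cell_ids),):
            raise ValidationError(f"group {self.name!r}: one ranking score per member required")

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.cell_ids)


@dataclass
class GroupOverlap:
    """Pairwise intersections, private counts and per-cell memberships."""

    group_names: list[str]
    pairwise: dict[tuple[str, str], int]
    privates: dict[str, int]
    membership: dict[str, list[str]]
    sizes: dict[str, int]

    def pair(self, a: str, b: str) -> int:
        return self.pairwise[tuple(sorted((a, b)))]

    def pair_fraction(self, a: str, b: str) -> float:
        """Shared cells as a fraction of the smaller group."""
        return self.pair(a, b) / min(self.sizes[a], self.sizes[b])

    def pair_jaccard(self, a: str, b: str) -> float:
        inter = self.pair(a, b)
        return inter / (self.sizes[a] + self.sizes[b] - inter)

    def exclusive_counts(self) -> dict[frozenset[str], int]:
        """Upset-style decomposition: count of cells per exact membership combination."""
        out: dict[frozenset[str], int] = {}
        for _cell, gs in self.membership.items():
            key = frozenset(gs)
            out[key] = out.get(key, 0) + 1
        return out


@dataclass
class MmrReport:
    """Max/min score ratio per group with Tukey-fence outlier flags."""

    mmr: dict[str, float]
    flagged: list[str]
    fences: tuple[float, float]


# ---------------------------------------------------------------------------


def top_fraction(
    scores: CellScores,
    fraction: float = 0.02,
    *,
    name: str | None = None,
    kind: str = "signature",
) -> CellGroup:
    """Select the top ``ceil(fraction * N)`` cells by score.

    Boundary ties are broken toward the lexicographically smallest cell id
    so the call is deterministic.
    """
    if not 0 < fraction < 1:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    n = len(scores.cell_ids)
    k = math.ceil(fraction * n)
    if k == 0 or n == 0:
        raise ValidationError("selection is empty; increase fraction or cell count")
    order = sorted(range(n), key=lambda i: (-scores.values[i], scores.cell_ids[i]))
    chosen = order[:k]
    return CellGroup(
        name or scores.name,
        [scores.cell_ids[i] for i in chosen],
        scores.values[chosen],
        {"kind": kind, "source": scores.name, "fraction": fraction},
    )


def marker_group(m: ExpressionMatrix, gene: str, fraction: float = 0.02) -> CellGroup:
    """Top-fraction group on a single marker gene's expression.

    Cells must express the marker (value > 0) to be eligible: "highest
    expression" is meaningless among zeros, so a marker expressed in fewer
    than k cells is an error rather than a zero-padded group.
    """
    expr = m.gene_row(gene)  # raises KeyError with near matches if absent
    k = math.ceil(fraction * m.n_cells)
    if int((expr > 0).sum()) < k:
        raise ValidationError(
            f"marker {gene!r}: only {(expr > 0).sum()} cells express it, need {k}"
        )
    scores = CellScores(gene, list(m.cell_ids), expr, {"marker": gene})
    g = top_fraction(scores, fraction, name=gene, kind="marker")
    g.selector["source"] = gene
    return g


def mmr_check(groups: list[CellGroup], whisker: float = 1.5) -> MmrReport:
    """Screen group homogeneity by the max/min ratio of ranking scores.

    A group is flagged when its MMR falls outside the Tukey box-plot
    fences (type-7 quartiles, ``whisker``x IQR) of the MMR distribution
    across groups.  A single group cannot be an outlier of its own
    distribution, so it is never flagged.
    """
    mmrs: dict[str, float] = {}
    for g in groups:
        if (g.ranking_score <= 0).any():
            raise ValidationError(f"group {g.name!r} has non-positive ranking scores; MMR undefined")
        mmrs[g.name] = float(g.ranking_score.max() / g.ranking_score.min())
    vals = np.array(list(mmrs.values()))
    if len(vals) < 2:
        return MmrReport(mmrs, [], (float("-inf"), float("inf")))
    q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation (type 7)
    lo, hi = q1 - whisker * (q3 - q1), q3 + whisker * (q3 - q1)
    flagged = [name for name, v in mmrs.items() if v < lo or v > hi]
    return MmrReport(mmrs, flagged, (float(lo), float(hi)))


def shrink_to_homogeneous(
    groups: list[CellGroup], whisker: float = 1.5, max_iter: int = 100
) -> tuple[list[CellGroup], MmrReport]:
    """Iteratively drop the weakest member of each flagged group until no
    group is an MMR outlier.

    This is an optional refinement mode; the plain :func:`mmr_check` only
    reports flags.
    """
    current = list(groups)
    report = mmr_check(current, whisker)
    for _ in range(max_iter):
        if not report.flagged:
            break
        nxt = []
        for g in current:
            if g.name in report.flagged and len(g) > 2:
                order = np.argsort(-g.ranking_score, kind="stable")[:-1]
                nxt.append(
                    CellGroup(g.name, [g.cell_ids[i] for i in order], g.ranking_score[order], dict(g.selector))
                )
            else:
                nxt.append(g)
        current = nxt
        report = mmr_check(current, whisker)
    return current, report


def compute_overlap(groups: list[CellGroup]) -> GroupOverlap:
    """Exact pairwise/private/membership decomposition of >= 2 groups."""
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate group names")
    if len(groups) < 2:
        raise ValidationError("overlap needs at least two groups")
    members = {g.name: g.members for g in groups}
    pairwise = {
        tuple(sorted((a, b))): len(members[a] & members[b]) for a, b in combinations(names, 2)
    }
    membership: dict[str, list[str]] = {}
    for g in groups:
        for c in g.cell_ids:
            membership.setdefault(c, []).append(g.name)
    privates = {
        name: sum(1 for c in members[name] if len(membership[c]) == 1) for name in names
    }
    sizes = {name: len(members[name]) for name in names}
    return GroupOverlap(names, pairwise, privates, membership, sizes)


def private_cells(groups: list[CellGroup], g: str) -> set[str]:
    """Cells of group ``g`` that belong to no other group (the DEG cohorts)."""
    names = [x.name for x in groups]
    if g not in names:
        raise ValidationError(f"unknown group {g!r}; have {names}")
    target = next(x for x in groups if x.name == g)
    others: set[str] = set()
    for x in groups:
        if x.name != g:
            others |= x.members
    return set(target.members - others)


def combo_csc(marker_groups: list[CellGroup]) -> CellGroup:
    """Cells high for at least two CSC markers simultaneously.

    Defined over the five marker-high groups only; each member is annotated
    (in ``selector['pairs']``) with every marker pair it satisfies.
    """
    for g in marker_groups:
        if g.selector.get("kind") != "marker":
            raise ValidationError(
                f"combo_csc is defined over marker groups only; {g.name!r} has kind "
                f"{g.selector.get('kind')!r}"
            )
    counts: dict[str, list[str]] = {}
    for g in marker_groups:
        for c in g.cell_ids:
            counts.setdefault(c, []).append(g.name)
    members = sorted(c for c, gs in counts.items() if len(gs) >= 2)
    pairs = {c: [tuple(sorted(p)) for p in combinations(sorted(counts[c]), 2)] for c in members}
    return CellGroup(
        "Combo_CSC",
        members,
        np.array([float(len(counts[c])) for c in members]),
        {"kind": "combo", "source": "markers", "pairs": pairs},
    )
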