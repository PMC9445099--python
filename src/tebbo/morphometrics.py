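"""Morphometric measurement of organoid trees.

The conventions mirror how branched organoids are measured on microscopy
skeletons: terminal-branch width is read 30 µm behind the branch tip (at the
branch base when the branch is shorter than that), body width 100 µm behind
the tip, non-terminal width 100 µm behind the distal branching point (the
base of the "Y"), a branch is the segment between a tip and a branching point
(terminal) or between two branching points (non-terminal), and the organoid
major axis is approximated by the maximum pairwise distance between skeleton
nodes.

Simulated branches carry a single width; fixtures with per-node widths are
supported through the ``node_widths`` argument (linear interpolation along
arc length).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .spatial import Branch, OrganoidTree

__all__ = [
    "MorphometricRecord",
    "BodyWidth",
    "terminal_branch_width",
    "body_width",
    "count_branches",
    "major_axis_length",
    "normalized_volumetric_growth",
    "measure_tree",
    "RECORD_KINDS",
]

RECORD_KINDS = frozenset(
    {
        "terminal_width",
        "body_width",
        "nonterminal_width",
        "branch_length",
        "branch_count_terminal",
        "branch_count_nonterminal",
        "major_axis",
        "cell_count",
    }
)


@dataclass(frozen=True)
class MorphometricRecord:
    """One measured quantity on one branch (or whole organoid) at one time.

    Widths, lengths and the major axis are in µm; counts are dimensionless.
    """

    organoid_id: str
    time: float
    branch_id: int | None
    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in RECORD_KINDS:
            raise ValueError(f"unknown record kind {self.kind!r}")
        if self.value < 0:
            raise ValueError(f"record value must be >= 0, got {self.value}")


class BodyWidth(NamedTuple):
    value: float
    truncated: bool  # True when the branch was shorter than the offset


def _arc_lengths(nodes: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _width_at_offset(
    branch: Branch, offset: float, node_widths: Sequence[float] | None
) -> tuple[float, bool]:
    """Width at arc length ``offset`` behind the distal end of the branch.

    Returns ``(width, truncated)``; ``truncated`` means the branch is shorter
    than the offset and the width at the branch base was used instead.
    """
    if node_widths is None:
        # simulator branches are cylinders: width is uniform along the branch
        return branch.width, branch.length < offset
    widths = np.asarray(node_widths, dtype=float)
    if widths.shape[0] != branch.nodes.shape[0]:
        raise ValueError("node_widths must align with the branch polyline nodes")
    s = _arc_lengths(branch.nodes)
    total = s[-1]
    if total < offset:
        return float(widths[0]), True
    return float(np.interp(total - offset, s, widths)), False


def terminal_branch_width(
    tree: OrganoidTree,
    branch_id: int,
    offset: float = 30.0,
    node_widths: Sequence[float] | None = None,
) -> float:
    """Terminal-branch width measured ``offset`` µm behind the tip, µm.

    Branches shorter than ``offset`` are measured at the branch base, close to
    the branching point (the nascent-branch fallback).
    """
    branch = tree.branches[branch_id]
    if not branch.terminal:
        raise ValueError(f"branch {branch_id} is not terminal")
    if branch.broken:
        raise ValueError(f"branch {branch_id} is broken")
    value, _ = _width_at_offset(branch, offset, node_widths)
    return value


def body_width(
    tree: OrganoidTree,
    branch_id: int,
    offset: float = 100.0,
    node_widths: Sequence[float] | None = None,
) -> BodyWidth:
    """Branch "body" width ``offset`` µm behind the distal end, µm.

    For a terminal branch the distal end is the tip; for a non-terminal branch
    it is the branching point where its daughters meet (the base of the "Y"),
    so the measurement runs 100 µm down from that point. Branches shorter than
    the offset return the base width with ``truncated=True``.
    """
    branch = tree.branches[branch_id]
    value, truncated = _width_at_offset(branch, offset, node_widths)
    return BodyWidth(value, truncated)


def count_branches(tree: OrganoidTree) -> tuple[int, int]:
    """``(n_terminal, n_nonterminal)`` — exhaustive, disjoint classification."""
    n_term = sum(1 for b in tree.branches.values() if b.terminal)
    return n_term, len(tree.branches) - n_term


def major_axis_length(tree: OrganoidTree) -> float:
    """Maximum pairwise distance between skeleton nodes, µm.

    A skeleton proxy for the major axis of an ellipse fitted to an image mask;
    it upper-bounds the mask-based value.
    """
    pts = np.concatenate([b.nodes for b in tree.branches.values()])
    if pts.shape[0] == 0:
        raise ValueError("tree has no nodes")
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > 64:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (collinear) point sets: brute force below
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def normalized_volumetric_growth(v_start: float, v_end: float, delta_t: float) -> float:
    """Normalized volumetric growth rate (V(t+Δ) − V(t)) / (V(t) Δ), 1/day."""
    if delta_t <= 0:
        raise ValueError(f"delta_t must be > 0, got {delta_t}")
    if v_start <= 0:
        raise ValueError(f"starting volume must be > 0, got {v_start}")
    return (v_end - v_start) / (v_start * delta_t)


def measure_tree(
    tree: OrganoidTree,
    organoid_id: str,
    v_cell: float | None = None,
    tip_offset: float = 30.0,
    body_offset: float = 100.0,
) -> pd.DataFrame:
    """All standard measurements of one tree as a tidy table.

    Columns: organoid_id, time [day], branch_id, kind, value. Emits terminal
    and non-terminal widths, branch lengths, the two branch counts, the major
    axis, and (when ``v_cell`` is given) the organoid cell count
    ``total volume / v_cell``.
    """
    records: list[MorphometricRecord] = []

    def add(kind: str, value: float, branch_id: int | None = None):
        records.append(
            MorphometricRecord(
                organoid_id=organoid_id,
                time=tree.time,
                branch_id=branch_id,
                kind=kind,
                value=value,
            )
        )

    for b in tree.branches.values():
        if b.broken:
            continue
        if b.terminal:
            add("terminal_width", terminal_branch_width(tree, b.id, tip_offset), b.id)
        else:
            add("nonterminal_width", body_width(tree, b.id, body_offset).value, b.id)
        add("branch_length", b.length, b.id)

    n_term, n_nonterm = count_branches(tree)
    add("branch_count_terminal", float(n_term))
    add("branch_count_nonterminal", float(n_nonterm))
    add("major_axis", major_axis_length(tree))
    if v_cell is not None:
        add("cell_count", tree.total_volume / v_cell)

    return pd.DataFrame(
        [
            {
                "organoid_id": r.organoid_id,
                "time [day]": r.time,
                "branch_id": r.branch_id,
                "kind": r.kind,
                "value": r.value,
            }
            for r in records
        ]
    )
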