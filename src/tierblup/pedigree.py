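"""Pedigree reading, validation, topological ordering, and tier partitioning.

A pedigree is a list of (animal, sire, dam) records with opaque string
labels.  Internally animals are renumbered 0..n-1 in a topological order
(every known parent precedes its offspring), which is what the recursive
relationship-matrix algorithms require.  The multi-tier structure used by
the updating method is captured by :class:`TierPartition`: the disjoint
sets *d* (distant external ancestors), *a* (parents of current animals)
and *c* (current animals), with the structural requirement that no animal
in *d* is a parent — or a mate with common offspring — of any animal in
*c*.  That requirement is exactly what makes the (d, c) block of the
inverse numerator relationship matrix vanish, and with it the exactness
of the updated evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNKNOWN = -1

_MISSING_TOKENS = {"0", "NA", "", "."}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or partitions."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    labels : list of str
        User-facing animal labels, in internal (topological) order.
    sire, dam : ndarray of int
        Internal parent indices per animal, ``UNKNOWN`` (-1) if absent.
    index : dict
        Label -> internal position.
    """

    labels: list
    sire: np.ndarray
    dam: np.ndarray
    index: dict = field(init=False)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if len(self.labels) != self.sire.size or self.sire.size != self.dam.size:
            raise PedigreeError("labels/sire/dam length mismatch")
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self.index) != len(self.labels):
            raise PedigreeError("duplicate animal id")
        # parents must precede offspring
        pos = np.arange(self.n)
        for par in (self.sire, self.dam):
            known = par >= 0
            if np.any(par[known] >= pos[known]):
                bad = int(np.nonzero(known & (par >= pos))[0][0])
                raise PedigreeError(
                    f"pedigree not topologically ordered at animal {self.labels[bad]!r}"
                )

    @property
    def n(self) -> int:
        return len(self.labels)

    def parents_of(self, i: int) -> tuple:
        return int(self.sire[i]), int(self.dam[i])

    def to_frame(self) -> pd.DataFrame:
        def lab(j):
            return self.labels[j] if j >= 0 else "0"

        return pd.DataFrame(
            {
                "animal": self.labels,
                "sire": [lab(s) for s in self.sire],
                "dam": [lab(d) for d in self.dam],
            }
        )

    def write(self, path) -> None:
        """Write TSV (animal/sire/dam, ``0`` = unknown) in topological order."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def _toposort(labels: Sequence, sire_lab: Sequence, dam_lab: Sequence) -> Pedigree:
    """Order records so parents precede offspring; detect cycles."""
    index = {}
    for lab in labels:
        if lab in index:
            raise PedigreeError(f"duplicate animal id {lab!r}")
        index[lab] = len(index)
    n = len(labels)
    parents = []
    for lab, s, d in zip(labels, sire_lab, dam_lab):
        if s == lab or d == lab:
            raise PedigreeError(f"animal {lab!r} is its own parent")
        parents.append(
            (index[s] if s is not None else UNKNOWN, index[d] if d is not None else UNKNOWN)
        )

    # Kahn's algorithm on the parent->offspring DAG
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i, (s, d) in enumerate(parents):
        for p in (s, d):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    order = [i for i in range(n) if indeg[i] == 0]
    head = 0
    while head < len(order):
        i = order[head]
        head += 1
        for ch in children[i]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                order.append(ch)
    if len(order) < n:
        cyc = next(lab for lab, deg in zip(labels, indeg) if deg > 0)
        raise PedigreeError(f"pedigree contains a cycle involving animal {cyc!r}")

    newpos = np.empty(n, dtype=np.int64)
    newpos[np.asarray(order)] = np.arange(n)
    new_labels = [labels[i] for i in order]
    sire = np.array(
        [newpos[parents[i][0]] if parents[i][0] >= 0 else UNKNOWN for i in order]
    )
    dam = np.array(
        [newpos[parents[i][1]] if parents[i][1] >= 0 else UNKNOWN for i in order]
    )
    return Pedigree(new_labels, sire, dam)


def build_pedigree(records: Iterable[tuple]) -> Pedigree:
    """Build an ordered :class:`Pedigree` from (animal, sire, dam) label triples.

    ``None`` or any of ``{"0", "NA", "", "."}`` marks an unknown parent.
    Parents never declared as animals are auto-registered as founders
    (with a warning), matching common pedigree-file practice.
    """
    recs = [(str(a), _norm(s), _norm(d)) for a, s, d in records]
    declared = {a for a, _, _ in recs}
    extra = []
    for _, s, d in recs:
        for p in (s, d):
            if p is not None and p not in declared:
                declared.add(p)
                extra.append(p)
    if extra:
        warnings.warn(
            f"{len(extra)} parent id(s) never declared as animals; "
            f"registered as founders: {extra[:5]}{'...' if len(extra) > 5 else ''}",
            stacklevel=2,
        )
    all_recs = [(p, None, None) for p in extra] + recs
    labels = [r[0] for r in all_recs]
    return _toposort(labels, [r[1] for r in all_recs], [r[2] for r in all_recs])


def _norm(tok):
    if tok is None:
        return None
    tok = str(tok)
    return None if tok in _MISSING_TOKENS else tok


def read_pedigree(path) -> Pedigree:
    """Read a pedigree TSV with header ``animal  sire  dam``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["animal", "sire", "dam"]
    if list(df.columns[:3]) != required:
        raise PedigreeError(
            f"{path}: expected columns {required}, found {list(df.columns)}"
        )
    return build_pedigree(df[required].itertuples(index=False, name=None))


@dataclass
class TierPartition:
    """Disjoint index sets d / a / c over a pedigree, in internal order.

    ``d``: distant external ancestors; ``a``: parents of current animals
    (the information channel); ``c``: current animals.  ``e = d ∪ a`` is
    the external set.
    """

    ped: Pedigree
    d_idx: np.ndarray
    a_idx: np.ndarray
    c_idx: np.ndarray

    @property
    def e_idx(self) -> np.ndarray:
        return np.sort(np.concatenate([self.d_idx, self.a_idx]))

    def labels(self, which: str) -> list:
        idx = {"d": self.d_idx, "a": self.a_idx, "c": self.c_idx}[which]
        return [self.ped.labels[i] for i in idx]


def partition_tiers(ped: Pedigree, current_ids: Iterable) -> TierPartition:
    """Partition a pedigree into d / a / c given the current-animal labels.

    ``a`` is the set of known parents of current animals that are not
    themselves current; ``d`` is everything else.  Raises
    :class:`PedigreeError` when the structural condition fails: a current
    animal must not be a parent of any external animal, and every known
    parent of a current animal must lie in ``a ∪ c`` — violations would
    break the exactness of the updated evaluation, so they are hard
    errors, not warnings.
    """
    current = set(map(str, current_ids))
    missing = current - set(ped.index)
    if missing:
        raise PedigreeError(f"current ids absent from pedigree: {sorted(missing)[:5]}")
    is_c = np.zeros(ped.n, dtype=bool)
    for lab in current:
        is_c[ped.index[lab]] = True

    is_a = np.zeros(ped.n, dtype=bool)
    for i in np.nonzero(is_c)[0]:
        for p in ped.parents_of(i):
            if p >= 0 and not is_c[p]:
                is_a[p] = True

    # no current animal may parent an external (non-current) animal
    for i in np.nonzero(~is_c)[0]:
        for p in ped.parents_of(i):
            if p >= 0 and is_c[p]:
                raise PedigreeError(
                    f"current animal {ped.labels[p]!r} is a parent of external "
                    f"animal {ped.labels[i]!r}; the tier structure is invalid"
                )

    part = TierPartition(
        ped,
        d_idx=np.nonzero(~is_c & ~is_a)[0],
        a_idx=np.nonzero(is_a)[0],
        c_idx=np.nonzero(is_c)[0],
    )
    validate_partition(part)
    return part


def validate_partition(part: TierPartition) -> None:
    """Check the d/a/c invariants; raise :class:`PedigreeError` on failure."""
    ped = part.ped
    n = ped.n
    tier = np.full(n, -1, dtype=np.int64)  # 0=d, 1=a, 2=c
    for t, idx in enumerate((part.d_idx, part.a_idx, part.c_idx)):
        if np.any(tier[idx] >= 0):
            raise PedigreeError("d/a/c sets are not disjoint")
        tier[idx] = t
    if np.any(tier < 0):
        raise PedigreeError("d/a/c sets do not cover the pedigree")

    parent_of_c = np.zeros(n, dtype=bool)
    for i in part.c_idx:
        for p in ped.parents_of(i):
            if p >= 0:
                if tier[p] == 0:
                    raise PedigreeError(
                        f"current animal {ped.labels[i]!r} has parent "
                        f"{ped.labels[p]!r} in the distant set d; the (d,c) "
                        "inverse-relationship block would not vanish"
                    )
                parent_of_c[p] = True
    for i in part.a_idx:
        if not parent_of_c[i]:
            raise PedigreeError(
                f"animal {ped.labels[i]!r} in set a is not a parent of any current animal"
            )


def extract_subpedigree(ped: Pedigree, ids: Iterable, mode: str = "clip-parents") -> Pedigree:
    """Extract the sub-pedigree over ``ids``.

    mode="clip-parents": keep exactly ``ids``; parents outside become unknown.
    mode="include-ancestors": close ``ids`` under the parent relation first.
    """
    if mode not in ("clip-parents", "include-ancestors"):
        raise ValueError(f"unknown mode {mode!r}")
    keep = set()
    for lab in ids:
        lab = str(lab)
        if lab not in ped.index:
            raise PedigreeError(f"id {lab!r} not in pedigree")
        keep.add(ped.index[lab])
    if mode == "include-ancestors":
        stack = list(keep)
        while stack:
            i = stack.pop()
            for p in ped.parents_of(i):
                if p >= 0 and p not in keep:
                    keep.add(p)
                    stack.append(p)
    kept = np.sort(np.fromiter(keep, dtype=np.int64))
    newpos = {int(old): new for new, old in enumerate(kept)}

    def remap(p):
        return newpos.get(int(p), UNKNOWN) if p >= 0 else UNKNOWN

    return Pedigree(
        [ped.labels[i] for i in kept],
        np.array([remap(ped.sire[i]) for i in kept]),
        np.array([remap(ped.dam[i]) for i in kept]),
    )
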