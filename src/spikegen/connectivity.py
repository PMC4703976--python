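"""Synaptic connectivity storage and circular delay queues.

Two storage schemes are supported for a projection between a pre-synaptic
population of ``n_pre`` neurons and a post-synaptic population of ``n_post``
neurons:

* :class:`DenseProjection` — an all-to-all matrix; every (pre, post) pair is a
  synapse unless masked out by an explicit existence mask.
* :class:`SparseProjection` — YALE (CSR) format: a row-start pointer array of
  length ``n_pre + 1`` and a flat post-index array of length ``n_conn``.
  Per-synapse variables are flat arrays addressed by the synapse index, i.e.
  the position in the post-index array.

Axonal delays are realised by :class:`DelayQueue` (fixed-width numeric slots)
and :class:`SpikeQueue` (variable-length id lists per slot): circular buffers
of ``m`` slots whose pointer ``p`` advances as ``(p + 1) mod m`` once per
global step, so a read at offset ``d`` returns data written ``d`` steps ago.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "DenseProjection",
    "SparseProjection",
    "DelayQueue",
    "SpikeQueue",
    "build_sparse",
    "sparse_to_dense",
    "dense_to_sparse",
    "row_targets",
    "queue_write",
    "queue_read",
    "queue_advance",
]


class ConnectivityError(ValueError):
    """Raised for malformed connectivity constructions."""


class SparseProjection:
    """YALE-format sparse projection.

    ``row_start`` (length ``n_pre + 1``) gives, for each pre-synaptic neuron,
    the index of its first synapse in ``post_index``; ``post_index`` holds the
    post-synaptic target of every synapse.  Within each row the post indices
    are kept strictly increasing (canonical form), which fixes a reproducible
    iteration and accumulation order.
    """

    kind = "sparse"

    def __init__(self, n_pre: int, n_post: int, row_start, post_index):
        self.n_pre = int(n_pre)
        self.n_post = int(n_post)
        self.row_start = np.asarray(row_start, dtype=np.int64)
        self.post_index = np.asarray(post_index, dtype=np.int64)
        self._col_order = None  # lazy reverse (post-major) index
        self._col_start = None
        self._validate()

    # -- invariants ---------------------------------------------------
    def _validate(self) -> None:
        rs, pi = self.row_start, self.post_index
        if rs.shape != (self.n_pre + 1,):
            raise ConnectivityError(
                f"row_start must have length n_pre+1={self.n_pre + 1}, got {rs.shape}"
            )
        if rs[0] != 0 or rs[-1] != pi.size:
            raise ConnectivityError("row_start must begin at 0 and end at n_conn")
        if np.any(np.diff(rs) < 0):
            raise ConnectivityError("row_start must be non-decreasing")
        if pi.size and (pi.min() < 0 or pi.max() >= self.n_post):
            raise ConnectivityError("post_index entries out of range")
        for i in range(self.n_pre):
            row = pi[rs[i]: rs[i + 1]]
            if row.size > 1 and np.any(np.diff(row) <= 0):
                raise ConnectivityError(
                    f"post indices of pre neuron {i} not strictly increasing"
                )

    @property
    def n_conn(self) -> int:
        return int(self.post_index.size)

    def row_slice(self, pre_id: int) -> slice:
        if not 0 <= pre_id < self.n_pre:
            raise ConnectivityError(f"pre_id {pre_id} out of range [0, {self.n_pre})")
        return slice(int(self.row_start[pre_id]), int(self.row_start[pre_id + 1]))

    def out_degree(self) -> np.ndarray:
        return np.diff(self.row_start)

    def gather_rows(self, pre_ids: np.ndarray):
        """Flat synapse/pre/post index arrays for the given pre neurons.

        The concatenation follows ``pre_ids`` order, then ascending synapse
        index within each row — the engine's deterministic accumulation order
        (callers pass ``pre_ids`` sorted ascending).
        """
        pre_ids = np.asarray(pre_ids, dtype=np.int64)
        starts = self.row_start[pre_ids]
        counts = self.row_start[pre_ids + 1] - starts
        total = int(counts.sum())
        syn = np.empty(total, dtype=np.int64)
        pre_of = np.empty(total, dtype=np.int64)
        pos = 0
        for pid, s, c in zip(pre_ids, starts, counts):
            c = int(c)
            syn[pos: pos + c] = np.arange(s, s + c)
            pre_of[pos: pos + c] = pid
            pos += c
        return syn, pre_of, self.post_index[syn]

    def _build_col_index(self) -> None:
        # post-major (then pre ascending) ordering of synapse indices, for
        # iterating the incoming synapses of post-synaptic neurons.
        pre_of = np.repeat(np.arange(self.n_pre), self.out_degree())
        order = np.lexsort((pre_of, self.post_index))
        counts = np.bincount(self.post_index, minlength=self.n_post)
        col_start = np.zeros(self.n_post + 1, dtype=np.int64)
        np.cumsum(counts, out=col_start[1:])
        self._col_order = order
        self._col_start = col_start
        self._pre_of_syn = pre_of

    def gather_cols(self, post_ids: np.ndarray):
        """Flat synapse/pre/post index arrays of synapses onto ``post_ids``."""
        if self._col_order is None:
            self._build_col_index()
        post_ids = np.asarray(post_ids, dtype=np.int64)
        pieces = [
            self._col_order[self._col_start[p]: self._col_start[p + 1]]
            for p in post_ids
        ]
        syn = (
            np.concatenate(pieces)
            if pieces
            else np.empty(0, dtype=np.int64)
        )
        return syn, self._pre_of_syn[syn], self.post_index[syn]

    def pairs(self) -> list[tuple[int, int]]:
        out = []
        for i in range(self.n_pre):
            for j in self.post_index[self.row_slice(i)]:
                out.append((i, int(j)))
        return out


class DenseProjection:
    """All-to-all projection; per-synapse variables are n_pre x n_post arrays.

    An optional boolean existence ``mask`` restricts which (pre, post) pairs
    are treated as real synapses by snippet application; by default all
    ``n_pre * n_post`` synapses exist.  The synapse index of pair (i, j) is
    the row-major flat index ``i * n_post + j``.
    """

    kind = "dense"

    def __init__(self, n_pre: int, n_post: int, mask: np.ndarray | None = None):
        self.n_pre = int(n_pre)
        self.n_post = int(n_post)
        if mask is None:
            mask = np.ones((self.n_pre, self.n_post), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_pre, self.n_post):
            raise ConnectivityError(
                f"mask shape {mask.shape} != ({self.n_pre}, {self.n_post})"
            )
        self.mask = mask
        self._col_cache = None

    @property
    def n_conn(self) -> int:
        return int(self.mask.sum())

    def out_degree(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    def gather_rows(self, pre_ids: np.ndarray):
        pre_ids = np.asarray(pre_ids, dtype=np.int64)
        syn_list, pre_list = [], []
        for pid in pre_ids:
            cols = np.flatnonzero(self.mask[pid])
            syn_list.append(pid * self.n_post + cols)
            pre_list.append(np.full(cols.size, pid, dtype=np.int64))
        if syn_list:
            syn = np.concatenate(syn_list)
            pre_of = np.concatenate(pre_list)
        else:
            syn = np.empty(0, dtype=np.int64)
            pre_of = np.empty(0, dtype=np.int64)
        return syn, pre_of, syn % self.n_post

    def gather_cols(self, post_ids: np.ndarray):
        post_ids = np.asarray(post_ids, dtype=np.int64)
        syn_list, pre_list, post_list = [], [], []
        for p in post_ids:
            rows = np.flatnonzero(self.mask[:, p])
            syn_list.append(rows * self.n_post + p)
            pre_list.append(rows)
            post_list.append(np.full(rows.size, p, dtype=np.int64))
        if syn_list:
            return (
                np.concatenate(syn_list),
                np.concatenate(pre_list),
                np.concatenate(post_list),
            )
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), e.copy()

    def all_synapses(self):
        syn = np.flatnonzero(self.mask.ravel())
        return syn, syn // self.n_post, syn % self.n_post

    def pairs(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(self.mask)
        return list(zip(ii.tolist(), jj.tolist()))


# ----------------------------------------------------------------------
# constructors / converters


def build_sparse(
    n_pre: int,
    n_post: int,
    pairs: Sequence[tuple[int, int]],
    values: Sequence[float] | None = None,
):
    """Build a canonical YALE projection from (pre, post) pairs.

    Pairs may arrive in any order; they are sorted pre-major then post-minor.
    ``values``, if given, are permuted consistently and returned alongside.
    Duplicate pairs and out-of-range indices are rejected.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if pairs.size:
        if pairs[:, 0].min() < 0 or pairs[:, 0].max() >= n_pre:
            raise ConnectivityError("pre index out of range")
        if pairs[:, 1].min() < 0 or pairs[:, 1].max() >= n_post:
            raise ConnectivityError("post index out of range")
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    srt = pairs[order]
    if srt.shape[0] > 1:
        dup = np.all(np.diff(srt, axis=0) == 0, axis=1)
        if np.any(dup):
            i, j = srt[int(np.flatnonzero(dup)[0])]
            raise ConnectivityError(f"duplicate synapse pair ({i}, {j})")
    counts = np.bincount(srt[:, 0], minlength=n_pre) if srt.size else np.zeros(n_pre, int)
    row_start = np.zeros(n_pre + 1, dtype=np.int64)
    np.cumsum(counts, out=row_start[1:])
    sp = SparseProjection(n_pre, n_post, row_start, srt[:, 1])
    if values is None:
        return sp
    values = np.asarray(values)
    if values.shape[0] != pairs.shape[0]:
        raise ConnectivityError("values length must match number of pairs")
    return sp, values[order]


def sparse_to_dense(sp: SparseProjection, values=None, fill=0.0):
    """Expand to a dense projection (existence mask induced by the pairs).

    Returns ``(DenseProjection, dense_values)`` when per-synapse ``values``
    are supplied, else just the projection.
    """
    mask = np.zeros((sp.n_pre, sp.n_post), dtype=bool)
    syn, pre_of, post_of = (
        np.arange(sp.n_conn),
        np.repeat(np.arange(sp.n_pre), sp.out_degree()),
        sp.post_index,
    )
    mask[pre_of, post_of] = True
    dn = DenseProjection(sp.n_pre, sp.n_post, mask)
    if values is None:
        return dn
    values = np.asarray(values)
    dense_vals = np.full((sp.n_pre, sp.n_post), fill, dtype=values.dtype)
    dense_vals[pre_of, post_of] = values[syn]
    return dn, dense_vals


def dense_to_sparse(dn: DenseProjection, values=None):
    """Collapse a (masked) dense projection back to canonical YALE form."""
    ii, jj = np.nonzero(dn.mask)  # row-major => pre-major, post ascending
    counts = np.bincount(ii, minlength=dn.n_pre)
    row_start = np.zeros(dn.n_pre + 1, dtype=np.int64)
    np.cumsum(counts, out=row_start[1:])
    sp = SparseProjection(dn.n_pre, dn.n_post, row_start, jj)
    if values is None:
        return sp
    values = np.asarray(values)
    if values.shape != (dn.n_pre, dn.n_post):
        raise ConnectivityError("dense values must have shape (n_pre, n_post)")
    return sp, values[ii, jj]


def row_targets(sp: SparseProjection, pre_id: int):
    """Post indices reached by ``pre_id`` and the matching synapse-index range."""
    sl = sp.row_slice(pre_id)
    return sp.post_index[sl], sl


# ----------------------------------------------------------------------
# delay queues


class DelayQueue:
    """Circular buffer of ``m`` slots x ``n`` numeric entries.

    Entry ``i`` of the current step lives at flat index ``n*p + i``; a read at
    delay ``d`` returns slot ``(p - d) mod m``.  The pointer advances once per
    global step.
    """

    def __init__(self, m: int, n: int, dtype=np.float64):
        if m < 1:
            raise ConnectivityError("delay queue needs at least one slot")
        self.m = int(m)
        self.n = int(n)
        self.buffer = np.zeros(self.m * self.n, dtype=dtype)
        self.p = 0

    def write(self, entries) -> None:
        entries = np.asarray(entries)
        if entries.shape != (self.n,):
            raise ConnectivityError(f"expected {self.n} entries, got {entries.shape}")
        self.buffer[self.n * self.p: self.n * (self.p + 1)] = entries

    def read(self, d: int) -> np.ndarray:
        if not 0 <= d < self.m:
            raise ConnectivityError(f"delay {d} outside [0, {self.m})")
        s = (self.p - d) % self.m
        return self.buffer[self.n * s: self.n * (s + 1)]

    def advance(self) -> None:
        self.p = (self.p + 1) % self.m


class SpikeQueue:
    """DelayQueue variant holding a variable-length id list per slot."""

    def __init__(self, m: int):
        if m < 1:
            raise ConnectivityError("spike queue needs at least one slot")
        self.m = int(m)
        self.slots: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(m)]
        self.p = 0

    def write(self, ids: np.ndarray) -> None:
        self.slots[self.p] = np.asarray(ids, dtype=np.int64)

    def read(self, d: int) -> np.ndarray:
        if not 0 <= d < self.m:
            raise ConnectivityError(f"delay {d} outside [0, {self.m})")
        return self.slots[(self.p - d) % self.m]

    def advance(self) -> None:
        self.p = (self.p + 1) % self.m
        self.slots[self.p] = np.empty(0, dtype=np.int64)


def queue_write(q, entries) -> None:
    q.write(entries)


def queue_read(q, d: int):
    return q.read(d)


def queue_advance(q) -> None:
    q.advance()
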