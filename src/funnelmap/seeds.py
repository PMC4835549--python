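"""Gapped spaced seeding (stage I, seed lookup).

A *shape* is a pattern over ``{1,0}`` where ``1`` marks an inclusive base and
``0`` a "don't care" (DC) base.  The reference index stores, for every
position, the key formed by concatenating the bases under the inclusive
positions (DC bases skipped).  At lookup time each DC position independently
admits three layouts so that a key tolerates a substitution, a 1 bp deletion
or a 1 bp insertion at that position:

* mismatch layout — skip the DC base (identical to indexing);
* deletion layout — do not skip it, consuming one fewer base overall;
* insertion layout — skip the DC base and the following base.

The Cartesian product over DC positions yields up to ``3^d`` lookup keys per
position per shape (deduplicated).  Two complementary shapes are used by
default: ``1111110111111`` (6-1-6) and ``11110111101111`` (4-1-4-1-4), both of
weight 12.

Only the forward strand is indexed; reads are queried both as-is and
reverse-complemented, with the strand recorded on every hit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from ._dna import encode, revcomp

logger = logging.getLogger(__name__)

#: The two default complementary shapes (6-1-6 and 4-1-4-1-4).
DEFAULT_SHAPES = ("1111110111111", "11110111101111")

#: Lookup keys seen in more postings than this are skipped (noise control).
DEFAULT_POSTING_CAP = 500


class ShapeError(ValueError):
    """Raised for a malformed spaced-seed pattern."""


@dataclass(frozen=True)
class Shape:
    """A spaced-seed shape: inclusive ('1') and don't-care ('0') positions."""

    pattern: str

    @property
    def weight(self) -> int:
        """Number of inclusive positions (key length)."""
        return self.pattern.count("1")

    @property
    def dc_count(self) -> int:
        """Number of don't-care positions."""
        return self.pattern.count("0")

    @property
    def span(self) -> int:
        """Bases consumed by the indexing layout."""
        return len(self.pattern)

    def inclusive_offsets(self) -> np.ndarray:
        return np.flatnonzero(np.frombuffer(self.pattern.encode(), np.uint8) == ord("1"))

    def dc_offsets(self) -> np.ndarray:
        return np.flatnonzero(np.frombuffer(self.pattern.encode(), np.uint8) == ord("0"))

    def lookup_layouts(self) -> list[np.ndarray]:
        """All per-DC layout combinations as inclusive-offset vectors.

        Each layout is an array of offsets (relative to the seed start) of the
        bases used to build the key; the first layout is always the indexing
        (all-mismatch) layout.  For each DC position a choice shifts every
        later offset: deletion by -1, insertion by +1.
        """
        base = self.inclusive_offsets()
        dcs = self.dc_offsets()
        layouts = []
        for choices in itertools.product((0, -1, +1), repeat=len(dcs)):
            offs = base.copy()
            for dc, shift in zip(dcs, choices):
                if shift:
                    offs = offs + np.where(base > dc, shift, 0)
            layouts.append(offs)
        return layouts


def parse_shape(pattern: str) -> Shape:
    """Validate and construct a :class:`Shape` from a ``{1,0}`` pattern."""
    if not pattern:
        raise ShapeError("empty shape pattern")
    for i, ch in enumerate(pattern):
        if ch not in "10":
            raise ShapeError(f"invalid character {ch!r} at position {i} in shape {pattern!r}")
    if pattern[0] != "1" or pattern[-1] != "1":
        raise ShapeError(f"shape {pattern!r} must begin and end with '1'")
    return Shape(pattern)


@dataclass(frozen=True)
class SeedHit:
    """A single seed hit: read position, reference position, strand."""

    qpos: int
    tpos: int
    strand: str = "+"
    shape_id: int = 0
    ref_id: int = 0


def index_key(seq: str, pos: int, shape: Shape) -> str | None:
    """Key used at indexing time: inclusive bases only, DC bases skipped.

    Returns ``None`` if any inclusive base is not A/C/G/T.  Raises
    ``IndexError`` when the shape does not fit at ``pos``.
    """
    if pos < 0 or pos + shape.span > len(seq):
        raise IndexError(f"shape span {shape.span} does not fit at position {pos}")
    key = "".join(seq[pos + o].upper() for o in shape.inclusive_offsets())
    return key if all(c in "ACGT" for c in key) else None


def lookup_keys(seq: str, pos: int, shape: Shape) -> set[str]:
    """All lookup keys for the seed at ``pos`` (mismatch/deletion/insertion
    layouts per DC position, Cartesian product, deduplicated).

    Layouts extending past the end of ``seq`` are silently omitted.
    """
    keys: set[str] = set()
    n = len(seq)
    truncated = False
    for offs in shape.lookup_layouts():
        if pos < 0 or pos + int(offs[-1]) + 1 > n:
            truncated = True
            continue
        key = "".join(seq[pos + int(o)].upper() for o in offs)
        if all(c in "ACGT" for c in key):
            keys.add(key)
    if truncated:
        logger.debug("lookup at pos %d: some layouts truncated at sequence end", pos)
    return keys


def _pack_keys(codes: np.ndarray, offsets: np.ndarray, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pack keys at ``positions`` as integers; drop keys touching non-ACGT.

    Returns (valid positions, packed keys), 2 bits per inclusive base.
    """
    if len(positions) == 0:
        return positions, np.zeros(0, dtype=np.int64)
    gather = codes[positions[:, None] + offsets[None, :]]
    ok = (gather < 4).all(axis=1)
    gather = gather[ok].astype(np.int64)
    shifts = (2 * np.arange(len(offsets), dtype=np.int64))[::-1]
    keys = (gather << shifts[None, :]).sum(axis=1)
    return positions[ok], keys


def _key_to_int(key: str) -> int:
    v = 0
    for c in key:
        v = (v << 2) | "ACGT".index(c)
    return v


class SeedIndex:
    """Postings of one shape over a set of reference sequences.

    Internally keys are packed 2-bit integers kept in a sorted array with
    parallel position / reference-id arrays; lookup is a binary search.
    """

    def __init__(self, shape: Shape, names: list[str], lengths: list[int]):
        self.shape = shape
        self.names = names
        self.lengths = lengths
        self._keys = np.zeros(0, dtype=np.int64)
        self._pos = np.zeros(0, dtype=np.int64)
        self._ref = np.zeros(0, dtype=np.int32)

    def _build(self, encoded: list[np.ndarray]) -> None:
        offs = self.shape.inclusive_offsets()
        span = self.shape.span
        all_keys, all_pos, all_ref = [], [], []
        for rid, codes in enumerate(encoded):
            n = len(codes) - span + 1
            if n <= 0:
                continue
            positions = np.arange(n, dtype=np.int64)
            positions, keys = _pack_keys(codes, offs, positions)
            all_keys.append(keys)
            all_pos.append(positions)
            all_ref.append(np.full(len(keys), rid, dtype=np.int32))
        if all_keys:
            keys = np.concatenate(all_keys)
            pos = np.concatenate(all_pos)
            ref = np.concatenate(all_ref)
            order = np.argsort(keys, kind="stable")
            self._keys, self._pos, self._ref = keys[order], pos[order], ref[order]

    def __len__(self) -> int:
        return len(self._keys)

    def postings(self, key: str) -> list[tuple[int, int]]:
        """(ref_id, position) pairs stored under a key string."""
        v = _key_to_int(key)
        lo = np.searchsorted(self._keys, v, side="left")
        hi = np.searchsorted(self._keys, v, side="right")
        return [(int(self._ref[i]), int(self._pos[i])) for i in range(lo, hi)]

    def lookup_ranges(self, keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._keys, keys, side="left")
        hi = np.searchsorted(self._keys, keys, side="right")
        return lo, hi


def build_index(references: list[tuple[str, str]], shapes: list[Shape]) -> list[SeedIndex]:
    """One :class:`SeedIndex` per shape over the forward strands."""
    if not references:
        raise ValueError("no reference sequences given")
    kept_names, kept_seqs = [], []
    for name, seq in references:
        if not seq:
            logger.warning("reference %r is empty; skipped", name)
            continue
        kept_names.append(name)
        kept_seqs.append(seq)
    encoded = [encode(s) for s in kept_seqs]
    lengths = [len(s) for s in kept_seqs]
    indexes = []
    for shape in shapes:
        idx = SeedIndex(shape, kept_names, lengths)
        idx._build(encoded)
        indexes.append(idx)
    return indexes


def _ranges_concat(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Concatenate integer ranges [lo_i, hi_i) into one index array."""
    lens = hi - lo
    total = int(lens.sum())
    if total == 0:
        return np.zeros(0, dtype=np.int64)
    starts = np.repeat(lo, lens)
    within = np.arange(total, dtype=np.int64) - np.repeat(
        np.concatenate(([0], np.cumsum(lens)[:-1])), lens
    )
    return starts + within


def _strand_hit_arrays(
    read_codes: np.ndarray, index: SeedIndex, cap: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (qpos, tpos, ref_id) hits of one oriented read against one index.

    Keys arising from different DC layouts at the same read position are
    deduplicated before lookup; keys with more than ``cap`` postings are
    skipped.
    """
    layouts = index.shape.lookup_layouts()
    n = len(read_codes)
    keymat = np.full((len(layouts), n), -1, dtype=np.int64)
    for li, offs in enumerate(layouts):
        span = int(offs[-1]) + 1
        m = n - span + 1
        if m <= 0:
            continue
        positions = np.arange(m, dtype=np.int64)
        positions, keys = _pack_keys(read_codes, offs, positions)
        keymat[li, positions] = keys
    # per-position dedup across layouts
    keymat.sort(axis=0)
    dup = np.zeros_like(keymat, dtype=bool)
    dup[1:] = keymat[1:] == keymat[:-1]
    valid = (keymat >= 0) & ~dup
    qpos_all = np.broadcast_to(np.arange(n, dtype=np.int64), keymat.shape)[valid]
    keys_all = keymat[valid]
    lo, hi = index.lookup_ranges(keys_all)
    counts = hi - lo
    sel = (counts > 0) & (counts <= cap)
    lo, hi, qsel = lo[sel], hi[sel], qpos_all[sel]
    idx = _ranges_concat(lo, hi)
    qpos = np.repeat(qsel, (hi - lo))
    return qpos, index._pos[idx], index._ref[idx]


def collect_hit_arrays(
    read: str, indexes: list[SeedIndex], cap: int = DEFAULT_POSTING_CAP
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Hits of a read (both orientations) against every index, as arrays.

    Returns ``{strand: (qpos, tpos, ref_id)}``.  For the '-' strand, qpos is
    a coordinate on the reverse-complemented read.
    """
    out = {}
    for strand, seq in (("+", read), ("-", revcomp(read))):
        codes = encode(seq)
        qs, ts, rs = [], [], []
        for index in indexes:
            q, t, r = _strand_hit_arrays(codes, index, cap)
            qs.append(q)
            ts.append(t)
            rs.append(r)
        out[strand] = (np.concatenate(qs), np.concatenate(ts), np.concatenate(rs))
    return out


def collect_hits(
    read: str, indexes: list[SeedIndex], cap: int = DEFAULT_POSTING_CAP
) -> list[SeedHit]:
    """Hits of a read against every index, as :class:`SeedHit` objects."""
    hits = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        codes = encode(seq)
        for sid, index in enumerate(indexes):
            q, t, r = _strand_hit_arrays(codes, index, cap)
            for qi, ti, ri in zip(q, t, r):
                hits.append(SeedHit(int(qi), int(ti), strand, shape_id=sid, ref_id=int(ri)))
    return hits
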