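"""Reading and writing ABIF trace containers (.fsa / .ab1 files).

ABIF is the tagged-record binary format written by ABI capillary
sequencers.  A file starts with the 4-byte magic ``ABIF`` and a version
word, followed (at byte 6) by a root directory entry pointing at a table
of 28-byte directory entries.  Each entry names a tag (4-character name
plus an integer number), an element type, and either inline data (when
the payload is at most 4 bytes) or an offset into the file.  Fragment
analysis runs (.fsa) store per-dye fluorescence signals as big-endian
signed 16-bit arrays under the ``DATA`` tag: raw channels at numbers
1-4 with the fifth (size-standard) channel at 105, analysed channels at
9-12 with the fifth at 205.

This module reads those containers into :class:`TraceRecord` objects and
writes them back either from scratch (a minimal valid file) or in
"patch" mode, where the original file bytes are kept and only the signal
records, matrix and directory are rewritten -- preserving every other
vendor tag byte-for-byte so downstream fragment-sizing software still
accepts the file.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace
from math import isqrt
from pathlib import Path

import numpy as np

MAGIC = b"ABIF"
ENTRY_SIZE = 28
_ROOT_OFFSET = 6
_ENTRY_STRUCT = struct.Struct(">4sihhii4s4s")

# element-type codes from the public ABIF specification
BYTE, CHAR, WORD, SHORT, LONG, FLOAT, DOUBLE = 1, 2, 3, 4, 5, 7, 8
PSTRING, CSTRING = 18, 19
DIRTYPE = 1023

RAW_CHANNEL_NUMBERS = (1, 2, 3, 4, 105)
ANALYSED_CHANNEL_NUMBERS = (9, 10, 11, 12, 205)
#: Historical tag names under which an inline spectral matrix may live.
MATRIX_TAG_NAMES = ("MTRX", "Mtrx")

INT16_MIN, INT16_MAX = -(2**15), 2**15 - 1

DEFAULT_DYE_NAMES = ("6-FAM", "VIC", "NED", "PET", "LIZ")


@dataclass
class AbifTag:
    """One decoded directory entry plus its payload bytes."""

    name: str
    number: int
    element_type: int
    element_size: int
    num_elements: int
    data: bytes
    raw_entry: bytes | None = None  # original 28 bytes, kept for patch mode

    def shorts(self) -> np.ndarray:
        return np.frombuffer(self.data, dtype=">i2").astype(np.int32)

    def floats(self) -> np.ndarray:
        return np.frombuffer(self.data, dtype=">f4").astype(np.float64)

    def string(self) -> str:
        if self.element_type == PSTRING:
            n = self.data[0] if self.data else 0
            return self.data[1 : 1 + n].decode("latin-1")
        return self.data.decode("latin-1").rstrip("\x00").strip()


@dataclass
class TraceRecord:
    """In-memory representation of one trace file.

    channels
        Up to 5 signal arrays, one value per scan.  Channels 1-4 carry
        the dye-labelled fragments; channel 5, when present, the size
        standard.  Values may be floats in memory (after normalisation);
        they are rounded and clipped to the signed 16-bit range on write.
    """

    channels: list[np.ndarray]
    model: str = "unknown"
    dye_names: list[str] = field(default_factory=list)
    matrix: np.ndarray | None = None
    source_bytes: bytes | None = None
    is_raw: bool = True
    #: (start, stop) scan span in the pre-trim coordinate system, set by trim().
    trim_span: tuple[int, int] | None = None

    @property
    def channel_count(self) -> int:
        return len(self.channels)

    @property
    def n_scans(self) -> int:
        return len(self.channels[0]) if self.channels else 0

    def data_channels(self) -> list[np.ndarray]:
        """The four dye-label channels (size standard excluded)."""
        return list(self.channels[:4])

    @property
    def ladder(self) -> np.ndarray | None:
        """The fifth (size-standard) channel, or None."""
        return self.channels[4] if len(self.channels) == 5 else None


def _unpack_entry(raw: bytes) -> tuple:
    name, number, etype, esize, nelem, dsize, doff, dhandle = _ENTRY_STRUCT.unpack(raw)
    return name.decode("latin-1"), number, etype, esize, nelem, dsize, doff, dhandle


def _pack_entry(
    name: str, number: int, etype: int, esize: int, nelem: int, dsize: int, doff: bytes
) -> bytes:
    return _ENTRY_STRUCT.pack(
        name.encode("latin-1"), number, etype, esize, nelem, dsize, doff, b"\x00" * 4
    )


def parse_tags(blob: bytes) -> tuple[int, list[AbifTag], int, int]:
    """Parse an ABIF blob into (version, tags, dir_offset, dir_size).

    Raises ValueError for a missing magic or a truncated directory.
    """
    if len(blob) < 4 or blob[:4] != MAGIC:
        raise ValueError("not an ABIF file: missing magic signature")
    if len(blob) < _ROOT_OFFSET + ENTRY_SIZE:
        raise ValueError("corrupt file: truncated header")
    version = struct.unpack(">h", blob[4:6])[0]
    root = _unpack_entry(blob[_ROOT_OFFSET : _ROOT_OFFSET + ENTRY_SIZE])
    _, _, _, _, n_entries, dir_size, dir_off_raw, _ = root
    dir_off = int.from_bytes(dir_off_raw, "big", signed=True)
    if n_entries < 0 or dir_off < 0 or dir_off + n_entries * ENTRY_SIZE > len(blob):
        raise ValueError("corrupt file: directory extends past end of file")
    tags: list[AbifTag] = []
    for i in range(n_entries):
        raw = blob[dir_off + ENTRY_SIZE * i : dir_off + ENTRY_SIZE * (i + 1)]
        name, number, etype, esize, nelem, dsize, doff_raw, _ = _unpack_entry(raw)
        if dsize <= 4:
            data = doff_raw[:dsize]
        else:
            start = int.from_bytes(doff_raw, "big", signed=True)
            if start < 0 or start + dsize > len(blob):
                raise ValueError(f"corrupt file: data of tag {name}{number} out of range")
            data = bytes(blob[start : start + dsize])
        tags.append(AbifTag(name, number, etype, esize, nelem, data, raw_entry=bytes(raw)))
    return version, tags, dir_off, dir_size


def read_trace(path: str | Path) -> TraceRecord:
    """Read an ABIF trace file into a :class:`TraceRecord`.

    Raw signal records (DATA 1-4, fifth at 105) are preferred over
    analysed ones (DATA 9-12, fifth at 205); ``is_raw`` records which
    set was used.  Channels of unequal length are truncated to the
    shortest with a warning.
    """
    blob = Path(path).read_bytes()
    _, tags, _, _ = parse_tags(blob)
    index = {(t.name, t.number): t for t in tags}

    if all(("DATA", n) in index for n in RAW_CHANNEL_NUMBERS[:4]):
        numbers, is_raw = RAW_CHANNEL_NUMBERS, True
    elif all(("DATA", n) in index for n in ANALYSED_CHANNEL_NUMBERS[:4]):
        numbers, is_raw = ANALYSED_CHANNEL_NUMBERS, False
    else:
        raise ValueError("unsupported channel layout: fewer than 4 signal channels")

    channels = [index[("DATA", n)].shorts() for n in numbers[:4]]
    fifth = index.get(("DATA", numbers[4]))
    if fifth is not None and len(fifth.data) >= 2:
        channels.append(fifth.shorts())

    if min(len(c) for c in channels[:4]) == 0:
        raise ValueError("corrupt file: empty signal record")
    lengths = {len(c) for c in channels}
    if len(lengths) > 1:
        m = min(lengths)
        warnings.warn(
            f"unequal channel lengths {sorted(lengths)}; truncating all to {m}",
            stacklevel=2,
        )
        channels = [c[:m] for c in channels]

    modl = index.get(("MODL", 1))
    if modl is not None:
        model = modl.string()
    else:
        model = "unknown"
        warnings.warn("no MODL tag: instrument model unknown", stacklevel=2)

    dye_names = []
    for i in range(1, 6):
        tag = index.get(("DyeN", i))
        if tag is None:
            break
        dye_names.append(tag.string())

    matrix = None
    for name in MATRIX_TAG_NAMES:
        tag = index.get((name, 1))
        if tag is None:
            continue
        vals = tag.floats() if tag.element_type == FLOAT else tag.shorts().astype(float)
        n = isqrt(vals.size)
        if n * n == vals.size and n > 0:
            matrix = vals.reshape(n, n)
            break
        warnings.warn(f"matrix tag {name} has non-square size {vals.size}; ignored", stacklevel=2)

    return TraceRecord(
        channels=channels,
        model=model,
        dye_names=dye_names,
        matrix=matrix,
        source_bytes=blob,
        is_raw=is_raw,
    )


def _encode_channel(values: np.ndarray, clip: bool) -> bytes:
    arr = np.rint(np.asarray(values, dtype=float))
    if clip:
        arr = np.clip(arr, INT16_MIN, INT16_MAX)
    elif arr.size and (arr.min() < INT16_MIN or arr.max() > INT16_MAX):
        raise OverflowError("overflow: channel value outside signed 16-bit range")
    return arr.astype(">i2").tobytes()


def _signal_replacements(record: TraceRecord, clip: bool) -> dict[tuple[str, int], tuple]:
    """Map (tag name, number) -> (etype, esize, nelem, payload) for this record."""
    numbers = RAW_CHANNEL_NUMBERS if record.is_raw else ANALYSED_CHANNEL_NUMBERS
    out: dict[tuple[str, int], tuple] = {}
    for i, ch in enumerate(record.channels[:5]):
        num = numbers[i] if i < 4 else numbers[4]
        out[("DATA", num)] = (SHORT, 2, len(ch), _encode_channel(ch, clip))
    return out


def _matrix_payload(matrix: np.ndarray) -> tuple:
    flat = np.asarray(matrix, dtype=">f4").tobytes()
    return (FLOAT, 4, matrix.size, flat)


def _write_fresh(record: TraceRecord, clip: bool) -> bytes:
    entries_spec: list[tuple[str, int, int, int, int, bytes]] = []
    for (name, num), (etype, esize, nelem, data) in _signal_replacements(record, clip).items():
        entries_spec.append((name, num, etype, esize, nelem, data))
    model = (record.model or "unknown").encode("latin-1")
    entries_spec.append(("MODL", 1, CHAR, 1, len(model), model))
    for i, dye in enumerate(record.dye_names[:5], start=1):
        payload = bytes([len(dye)]) + dye.encode("latin-1")
        entries_spec.append(("DyeN", i, PSTRING, 1, len(payload), payload))
    if record.matrix is not None:
        etype, esize, nelem, data = _matrix_payload(record.matrix)
        for name in MATRIX_TAG_NAMES:
            entries_spec.append((name, 1, etype, esize, nelem, data))

    data_start = 128  # real files leave headroom after the 34-byte header
    payload = bytearray()
    dir_bytes = bytearray()
    for name, num, etype, esize, nelem, data in entries_spec:
        dsize = len(data)
        if dsize <= 4:
            doff = data.ljust(4, b"\x00")
        else:
            doff = struct.pack(">i", data_start + len(payload))
            payload += data
        dir_bytes += _pack_entry(name, num, etype, esize, nelem, dsize, doff)

    dir_off = data_start + len(payload)
    blob = bytearray(data_start)
    blob[0:4] = MAGIC
    blob[4:6] = struct.pack(">h", 101)
    blob[_ROOT_OFFSET : _ROOT_OFFSET + ENTRY_SIZE] = _pack_entry(
        "tdir", 1, DIRTYPE, ENTRY_SIZE, len(entries_spec), len(dir_bytes), struct.pack(">i", dir_off)
    )
    return bytes(blob) + bytes(payload) + bytes(dir_bytes)


def _write_patched(record: TraceRecord, clip: bool) -> bytes:
    """Rewrite signal records (and matrix) of the original file bytes.

    All other tags keep their original payload bytes untouched; new or
    resized payloads are appended at the end and the directory is
    relocated after them.
    """
    assert record.source_bytes is not None
    _, tags, dir_off, dir_size = parse_tags(record.source_bytes)
    blob = bytearray(record.source_bytes)
    if dir_off + dir_size == len(blob):  # directory at the tail: drop the stale copy
        del blob[dir_off:]

    replacements = _signal_replacements(record, clip)
    if record.matrix is not None:
        for name in MATRIX_TAG_NAMES:
            replacements[(name, 1)] = _matrix_payload(record.matrix)
    if len(record.channels) == 5 and len(record.dye_names) >= 5:
        existing = {(t.name, t.number) for t in tags}
        if ("DyeN", 5) not in existing:
            dye = record.dye_names[4]
            payload = bytes([len(dye)]) + dye.encode("latin-1")
            replacements[("DyeN", 5)] = (PSTRING, 1, len(payload), payload)

    def emit(name: str, number: int, spec: tuple) -> bytes:
        etype, esize, nelem, data = spec
        dsize = len(data)
        if dsize <= 4:
            doff = data.ljust(4, b"\x00")
        else:
            doff = struct.pack(">i", len(blob))
            blob.extend(data)
        return _pack_entry(name, number, etype, esize, nelem, dsize, doff)

    dir_bytes = bytearray()
    n_entries = 0
    for tag in tags:
        key = (tag.name, tag.number)
        if key in replacements:
            dir_bytes += emit(tag.name, tag.number, replacements.pop(key))
        else:
            dir_bytes += tag.raw_entry
        n_entries += 1
    for (name, number), spec in replacements.items():  # tags absent from the source
        dir_bytes += emit(name, number, spec)
        n_entries += 1

    new_dir_off = len(blob)
    blob.extend(dir_bytes)
    blob[_ROOT_OFFSET : _ROOT_OFFSET + ENTRY_SIZE] = _pack_entry(
        "tdir", 1, DIRTYPE, ENTRY_SIZE, n_entries, len(dir_bytes), struct.pack(">i", new_dir_off)
    )
    return bytes(blob)


def write_trace(record: TraceRecord, path: str | Path, clip: bool = True) -> None:
    """Write a :class:`TraceRecord` to ``path`` as an ABIF file.

    When ``record.source_bytes`` is set the original file is patched
    (only signal records, matrix and directory change); otherwise a
    minimal valid ABIF file is emitted.  Channel values are rounded and
    clipped to the signed 16-bit range unless ``clip`` is False, in
    which case out-of-range values raise OverflowError.
    """
    if not record.channels:
        raise ValueError("ragged channels: record has no channels")
    lengths = {len(c) for c in record.channels}
    if len(lengths) > 1:
        raise ValueError(f"ragged channels: unequal lengths {sorted(lengths)}")
    blob = _write_patched(record, clip) if record.source_bytes is not None else _write_fresh(record, clip)
    Path(path).write_bytes(blob)


def copy_without_source(record: TraceRecord) -> TraceRecord:
    """A copy that will be written from scratch rather than patched."""
    return replace(record, source_bytes=None)
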