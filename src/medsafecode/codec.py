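"""The Medicine Safety Code itself: bit layout, base-64 payload, URL, QR.

A patient's panel genotypes are packed into a long binary number whose bit
fields follow the KB panel order.  Each marker gets a slot of
``ceil(log2(G + 1))`` bits, where ``G`` is the number of unordered diploid
pairs over its allowed nucleotides (3 for a biallelic SNP); index 0 always
means "genotype unknown" and indices 1..G enumerate the pairs in
lexicographic (min, max) order.  The bit string is padded with zeros to a
multiple of 6 and mapped 6 bits at a time through the base64url alphabet,
then embedded in a versioned URL::

    <base_url><version>/<payload>     e.g. http://safety-code.org/v0.2/QXGq...

This layout is a defined dialect of the code: the published example URLs of
the original web service are *parseable* here (``parse_url``) but not
*decodable*, because the original bit assignment was never published.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from . import _qr
from .errors import CapacityError, DecodeError, EncodeError, LayoutError, UrlParseError
from .genotype_io import UNKNOWN, Call, GenotypeProfile
from .kb import KnowledgeBase

#: URL-safe base-64 alphabet; character i encodes the 6-bit value i.
BASE64URL_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789-_"
_CHAR_VALUE = {ch: i for i, ch in enumerate(BASE64URL_ALPHABET)}

DEFAULT_BASE_URL = "http://safety-code.org/"

_VERSION_SEGMENT_RE = re.compile(r"(v\d+\.\d+)/")


@dataclass(frozen=True)
class Slot:
    """One marker's bit field in the code."""

    rsid: str
    bit_offset: int
    bit_width: int
    index_table: dict[Call, int]  # unordered pair (or UNKNOWN) -> slot value
    value_table: tuple[Call, ...]  # inverse: slot value -> pair / UNKNOWN


@dataclass(frozen=True)
class CodeLayout:
    """Deterministic bit layout over a KB panel."""

    slots: tuple[Slot, ...]
    total_bits: int
    version: str

    @property
    def payload_length(self) -> int:
        return math.ceil(self.total_bits / 6)


@dataclass(frozen=True)
class SafetyCode:
    """A versioned Medicine Safety Code: base URL + version + payload."""

    version: str
    payload: str
    base_url: str = DEFAULT_BASE_URL

    @property
    def url(self) -> str:
        return f"{self.base_url}{self.version}/{self.payload}"


def build_layout(kb: KnowledgeBase) -> CodeLayout:
    """Derive the code layout from the KB panel (a pure function of the KB)."""
    slots = []
    offset = 0
    for marker in kb.markers:
        if len(marker.allowed) > 4:
            raise LayoutError(f"marker {marker.rsid}: more than 4 allowed nucleotides")
        pairs = marker.pairs()
        width = math.ceil(math.log2(len(pairs) + 1))
        value_table: tuple[Call, ...] = (UNKNOWN, *pairs)
        index_table = {call: i for i, call in enumerate(value_table)}
        slots.append(Slot(marker.rsid, offset, width, index_table, value_table))
        offset += width
    return CodeLayout(slots=tuple(slots), total_bits=offset, version=kb.version)


def encode_profile(
    profile: GenotypeProfile,
    layout: CodeLayout,
    base_url: str = DEFAULT_BASE_URL,
) -> SafetyCode:
    """Pack a panel-restricted profile into a safety code.

    Slot values are written most-significant-bit first; the concatenated bit
    string is zero-padded to a multiple of 6 and mapped through the
    base64url alphabet.
    """
    bits: list[str] = []
    for slot in layout.slots:
        if slot.rsid not in profile.calls:
            raise EncodeError(f"profile lacks panel marker {slot.rsid}; restrict_to_panel first")
        call = profile.calls[slot.rsid]
        try:
            index = slot.index_table[call]
        except KeyError:
            raise EncodeError(
                f"marker {slot.rsid}: genotype {call!r} not representable "
                "(nucleotide outside the marker's allowed set)"
            ) from None
        bits.append(format(index, f"0{slot.bit_width}b"))
    bitstring = "".join(bits)
    bitstring += "0" * (-len(bitstring) % 6)
    payload = "".join(
        BASE64URL_ALPHABET[int(bitstring[i : i + 6], 2)] for i in range(0, len(bitstring), 6)
    )
    return SafetyCode(version=layout.version, payload=payload, base_url=base_url)


def decode_code(code: SafetyCode, layout: CodeLayout) -> GenotypeProfile:
    """Exact inverse of :func:`encode_profile` on the layout's panel."""
    if code.version != layout.version:
        raise DecodeError(
            f"code version {code.version!r} does not match layout version {layout.version!r}",
            kind="version",
        )
    bad = set(code.payload) - set(BASE64URL_ALPHABET)
    if bad:
        raise DecodeError(
            f"payload contains characters outside the base64url alphabet: {sorted(bad)}",
            kind="alphabet",
        )
    if len(code.payload) != layout.payload_length:
        raise DecodeError(
            f"payload length {len(code.payload)} does not match layout "
            f"({layout.payload_length} characters for {layout.total_bits} bits)",
            kind="length",
        )
    bitstring = "".join(format(_CHAR_VALUE[ch], "06b") for ch in code.payload)
    calls: dict[str, Call] = {}
    for slot in layout.slots:
        value = int(bitstring[slot.bit_offset : slot.bit_offset + slot.bit_width] or "0", 2)
        if value >= len(slot.value_table):
            raise DecodeError(
                f"marker {slot.rsid}: slot value {value} exceeds genotype table",
                kind="index",
            )
        calls[slot.rsid] = slot.value_table[value]
    if layout.total_bits and any(b != "0" for b in bitstring[layout.total_bits :]):
        raise DecodeError("non-zero padding bits after the last slot", kind="length")
    return GenotypeProfile(calls=calls, source_format="code")


def parse_url(url: str) -> SafetyCode:
    """Split a safety-code URL (or bare ``vX.Y/payload`` text) into parts."""
    m = _VERSION_SEGMENT_RE.search(url)
    if not m:
        raise UrlParseError(f"no /v<major>.<minor>/ version segment in {url!r}")
    base_url, version, payload = url[: m.start()], m.group(1), url[m.end() :]
    bad = set(payload) - set(BASE64URL_ALPHABET)
    if bad:
        raise DecodeError(
            f"payload contains characters outside the base64url alphabet: {sorted(bad)}",
            kind="alphabet",
        )
    return SafetyCode(version=version, payload=payload, base_url=base_url)


# ---------------------------------------------------------------------------
# QR rendering


def qr_capacity(version: int, ec_level: str) -> int:
    """Data capacity in bits of a QR symbol (8 x data codewords)."""
    return 8 * _qr.data_codewords(version, ec_level)


def render_qr(
    code: SafetyCode,
    out_path: Union[str, Path],
    ec_level: str = "M",
    scale: int = 4,
    border: int = 4,
) -> int:
    """Render the code's URL as a byte-mode QR PNG; return the symbol version.

    The smallest version whose data capacity holds the URL at the requested
    error-correction level is chosen.  Raises :class:`CapacityError` when the
    URL exceeds the version-40 capacity.
    """
    from PIL import Image

    data = code.url.encode("ascii")
    version = _qr.smallest_version(len(data), ec_level)
    if version is None:
        raise CapacityError(
            f"URL of {len(data)} bytes exceeds the byte-mode capacity of every "
            f"QR version at level {ec_level} "
            f"(version 40 holds {qr_capacity(40, ec_level)} bits)"
        )
    matrix = _qr.build_matrix(data, version, ec_level)
    size = len(matrix)
    img = Image.new("1", (size + 2 * border, size + 2 * border), 1)
    px = img.load()
    for r, row in enumerate(matrix):
        for c, v in enumerate(row):
            if v:
                px[border + c, border + r] = 0
    img = img.resize(((size + 2 * border) * scale,) * 2, Image.NEAREST)
    img.save(Path(out_path), format="PNG")
    return version
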