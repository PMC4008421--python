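"""Minimal QR symbol encoder (byte mode) with the standard capacity tables.

Implements the pieces of ISO/IEC 18004 needed to turn a short URL into a
scannable symbol: the per-version error-correction block structure, byte-mode
data encoding, Reed–Solomon error correction over GF(2^8) (polynomial 0x11D),
module placement, mask selection by penalty score, and format/version
information with their BCH codes.

The block-structure table below is transcribed from the standard; its
internal consistency is verifiable because for every version the total
codeword count (data + error correction) is fixed by symbol geometry and
must be identical across all four error-correction levels — see
:func:`symbol_total_codewords`, which derives that count from first
principles (module counts), independently of the table.
"""

from __future__ import annotations

from functools import lru_cache

EC_LEVELS = ("L", "M", "Q", "H")

# (version, level) -> (ec codewords per block, ((n_blocks, data_codewords), ...))
EC_BLOCKS: dict[tuple[int, str], tuple[int, tuple[tuple[int, int], ...]]] = {
    (1, "L"): (7, ((1, 19),)),
    (1, "M"): (10, ((1, 16),)),
    (1, "Q"): (13, ((1, 13),)),
    (1, "H"): (17, ((1, 9),)),
    (2, "L"): (10, ((1, 34),)),
    (2, "M"): (16, ((1, 28),)),
    (2, "Q"): (22, ((1, 22),)),
    (2, "H"): (28, ((1, 16),)),
    (3, "L"): (15, ((1, 55),)),
    (3, "M"): (26, ((1, 44),)),
    (3, "Q"): (18, ((2, 17),)),
    (3, "H"): (22, ((2, 13),)),
    (4, "L"): (20, ((1, 80),)),
    (4, "M"): (18, ((2, 32),)),
    (4, "Q"): (26, ((2, 24),)),
    (4, "H"): (16, ((4, 9),)),
    (5, "L"): (26, ((1, 108),)),
    (5, "M"): (24, ((2, 43),)),
    (5, "Q"): (18, ((2, 15), (2, 16))),
    (5, "H"): (22, ((2, 11), (2, 12))),
    (6, "L"): (18, ((2, 68),)),
    (6, "M"): (16, ((4, 27),)),
    (6, "Q"): (24, ((4, 19),)),
    (6, "H"): (28, ((4, 15),)),
    (7, "L"): (20, ((2, 78),)),
    (7, "M"): (18, ((4, 31),)),
    (7, "Q"): (18, ((2, 14), (4, 15))),
    (7, "H"): (26, ((4, 13), (1, 14))),
    (8, "L"): (24, ((2, 97),)),
    (8, "M"): (22, ((2, 38), (2, 39))),
    (8, "Q"): (22, ((4, 18), (2, 19))),
    (8, "H"): (26, ((4, 14), (2, 15))),
    (9, "L"): (30, ((2, 116),)),
    (9, "M"): (22, ((3, 36), (2, 37))),
    (9, "Q"): (20, ((4, 16), (4, 17))),
    (9, "H"): (24, ((4, 12), (4, 13))),
    (10, "L"): (18, ((2, 68), (2, 69))),
    (10, "M"): (26, ((4, 43), (1, 44))),
    (10, "Q"): (24, ((6, 19), (2, 20))),
    (10, "H"): (28, ((6, 15), (2, 16))),
    (11, "L"): (20, ((4, 81),)),
    (11, "M"): (30, ((1, 50), (4, 51))),
    (11, "Q"): (28, ((4, 22), (4, 23))),
    (11, "H"): (24, ((3, 12), (8, 13))),
    (12, "L"): (24, ((2, 92), (2, 93))),
    (12, "M"): (22, ((6, 36), (2, 37))),
    (12, "Q"): (26, ((4, 20), (6, 21))),
    (12, "H"): (28, ((7, 14), (4, 15))),
    (13, "L"): (26, ((4, 107),)),
    (13, "M"): (22, ((8, 37), (1, 38))),
    (13, "Q"): (24, ((8, 20), (4, 21))),
    (13, "H"): (22, ((12, 11), (4, 12))),
    (14, "L"): (30, ((3, 115), (1, 116))),
    (14, "M"): (24, ((4, 40), (5, 41))),
    (14, "Q"): (20, ((11, 16), (5, 17))),
    (14, "H"): (24, ((11, 12), (5, 13))),
    (15, "L"): (22, ((5, 87), (1, 88))),
    (15, "M"): (24, ((5, 41), (5, 42))),
    (15, "Q"): (30, ((5, 24), (7, 25))),
    (15, "H"): (24, ((11, 12), (7, 13))),
    (16, "L"): (24, ((5, 98), (1, 99))),
    (16, "M"): (28, ((7, 45), (3, 46))),
    (16, "Q"): (24, ((15, 19), (2, 20))),
    (16, "H"): (30, ((3, 15), (13, 16))),
    (17, "L"): (28, ((1, 107), (5, 108))),
    (17, "M"): (28, ((10, 46), (1, 47))),
    (17, "Q"): (28, ((1, 22), (15, 23))),
    (17, "H"): (28, ((2, 14), (17, 15))),
    (18, "L"): (30, ((5, 120), (1, 121))),
    (18, "M"): (26, ((9, 43), (4, 44))),
    (18, "Q"): (28, ((17, 22), (1, 23))),
    (18, "H"): (28, ((2, 14), (19, 15))),
    (19, "L"): (28, ((3, 113), (4, 114))),
    (19, "M"): (26, ((3, 44), (11, 45))),
    (19, "Q"): (26, ((17, 21), (4, 22))),
    (19, "H"): (26, ((9, 13), (16, 14))),
    (20, "L"): (28, ((3, 107), (5, 108))),
    (20, "M"): (26, ((3, 41), (13, 42))),
    (20, "Q"): (30, ((15, 24), (5, 25))),
    (20, "H"): (28, ((15, 15), (10, 16))),
    (21, "L"): (28, ((4, 116), (4, 117))),
    (21, "M"): (26, ((17, 42),)),
    (21, "Q"): (28, ((17, 22), (6, 23))),
    (21, "H"): (30, ((19, 16), (6, 17))),
    (22, "L"): (28, ((2, 111), (7, 112))),
    (22, "M"): (28, ((17, 46),)),
    (22, "Q"): (30, ((7, 24), (16, 25))),
    (22, "H"): (24, ((34, 13),)),
    (23, "L"): (30, ((4, 121), (5, 122))),
    (23, "M"): (28, ((4, 47), (14, 48))),
    (23, "Q"): (30, ((11, 24), (14, 25))),
    (23, "H"): (30, ((16, 15), (14, 16))),
    (24, "L"): (30, ((6, 117), (4, 118))),
    (24, "M"): (28, ((6, 45), (14, 46))),
    (24, "Q"): (30, ((11, 24), (16, 25))),
    (24, "H"): (30, ((30, 16), (2, 17))),
    (25, "L"): (26, ((8, 106), (4, 107))),
    (25, "M"): (28, ((8, 47), (13, 48))),
    (25, "Q"): (30, ((7, 24), (22, 25))),
    (25, "H"): (30, ((22, 15), (13, 16))),
    (26, "L"): (28, ((10, 114), (2, 115))),
    (26, "M"): (28, ((19, 46), (4, 47))),
    (26, "Q"): (28, ((28, 22), (6, 23))),
    (26, "H"): (30, ((33, 16), (4, 17))),
    (27, "L"): (30, ((8, 122), (4, 123))),
    (27, "M"): (28, ((22, 45), (3, 46))),
    (27, "Q"): (30, ((8, 23), (26, 24))),
    (27, "H"): (30, ((12, 15), (28, 16))),
    (28, "L"): (30, ((3, 117), (10, 118))),
    (28, "M"): (28, ((3, 45), (23, 46))),
    (28, "Q"): (30, ((4, 24), (31, 25))),
    (28, "H"): (30, ((11, 15), (31, 16))),
    (29, "L"): (30, ((7, 116), (7, 117))),
    (29, "M"): (28, ((21, 45), (7, 46))),
    (29, "Q"): (30, ((1, 23), (37, 24))),
    (29, "H"): (30, ((19, 15), (26, 16))),
    (30, "L"): (30, ((5, 115), (10, 116))),
    (30, "M"): (28, ((19, 47), (10, 48))),
    (30, "Q"): (30, ((15, 24), (25, 25))),
    (30, "H"): (30, ((23, 15), (25, 16))),
    (31, "L"): (30, ((13, 115), (3, 116))),
    (31, "M"): (28, ((2, 46), (29, 47))),
    (31, "Q"): (30, ((42, 24), (1, 25))),
    (31, "H"): (30, ((23, 15), (28, 16))),
    (32, "L"): (30, ((17, 115),)),
    (32, "M"): (28, ((10, 46), (23, 47))),
    (32, "Q"): (30, ((10, 24), (35, 25))),
    (32, "H"): (30, ((19, 15), (35, 16))),
    (33, "L"): (30, ((17, 115), (1, 116))),
    (33, "M"): (28, ((14, 46), (21, 47))),
    (33, "Q"): (30, ((29, 24), (19, 25))),
    (33, "H"): (30, ((11, 15), (46, 16))),
    (34, "L"): (30, ((13, 115), (6, 116))),
    (34, "M"): (28, ((14, 46), (23, 47))),
    (34, "Q"): (30, ((44, 24), (7, 25))),
    (34, "H"): (30, ((59, 16), (1, 17))),
    (35, "L"): (30, ((12, 121), (7, 122))),
    (35, "M"): (28, ((12, 47), (26, 48))),
    (35, "Q"): (30, ((39, 24), (14, 25))),
    (35, "H"): (30, ((22, 15), (41, 16))),
    (36, "L"): (30, ((6, 121), (14, 122))),
    (36, "M"): (28, ((6, 47), (34, 48))),
    (36, "Q"): (30, ((46, 24), (10, 25))),
    (36, "H"): (30, ((2, 15), (64, 16))),
    (37, "L"): (30, ((17, 122), (4, 123))),
    (37, "M"): (28, ((29, 46), (14, 47))),
    (37, "Q"): (30, ((49, 24), (10, 25))),
    (37, "H"): (30, ((24, 15), (46, 16))),
    (38, "L"): (30, ((4, 122), (18, 123))),
    (38, "M"): (28, ((13, 46), (32, 47))),
    (38, "Q"): (30, ((48, 24), (14, 25))),
    (38, "H"): (30, ((42, 15), (32, 16))),
    (39, "L"): (30, ((20, 117), (4, 118))),
    (39, "M"): (28, ((40, 47), (7, 48))),
    (39, "Q"): (30, ((43, 24), (22, 25))),
    (39, "H"): (30, ((10, 15), (67, 16))),
    (40, "L"): (30, ((19, 118), (6, 119))),
    (40, "M"): (28, ((18, 47), (31, 48))),
    (40, "Q"): (30, ((34, 24), (34, 25))),
    (40, "H"): (30, ((20, 15), (61, 16))),
}

# Alignment pattern centre coordinates per version (version 1 has none).
ALIGNMENT_POSITIONS: dict[int, tuple[int, ...]] = {
    1: (),
    2: (6, 18),
    3: (6, 22),
    4: (6, 26),
    5: (6, 30),
    6: (6, 34),
    7: (6, 22, 38),
    8: (6, 24, 42),
    9: (6, 26, 46),
    10: (6, 28, 50),
    11: (6, 30, 54),
    12: (6, 32, 58),
    13: (6, 34, 62),
    14: (6, 26, 46, 66),
    15: (6, 26, 48, 70),
    16: (6, 26, 50, 74),
    17: (6, 30, 54, 78),
    18: (6, 30, 56, 82),
    19: (6, 30, 58, 86),
    20: (6, 34, 62, 90),
    21: (6, 28, 50, 72, 94),
    22: (6, 26, 50, 74, 98),
    23: (6, 30, 54, 78, 102),
    24: (6, 28, 54, 80, 106),
    25: (6, 32, 58, 84, 110),
    26: (6, 30, 58, 86, 114),
    27: (6, 34, 62, 90, 118),
    28: (6, 26, 50, 74, 98, 122),
    29: (6, 30, 54, 78, 102, 126),
    30: (6, 26, 52, 78, 104, 130),
    31: (6, 30, 56, 82, 108, 134),
    32: (6, 34, 60, 86, 112, 138),
    33: (6, 30, 58, 86, 114, 142),
    34: (6, 34, 62, 90, 118, 146),
    35: (6, 30, 54, 78, 102, 126, 150),
    36: (6, 24, 50, 76, 102, 128, 154),
    37: (6, 28, 54, 80, 106, 132, 158),
    38: (6, 32, 58, 84, 110, 136, 162),
    39: (6, 26, 54, 82, 110, 138, 166),
    40: (6, 30, 58, 86, 114, 142, 170),
}


def _check_version_level(version: int, ec_level: str) -> None:
    if not 1 <= version <= 40:
        raise ValueError(f"QR version must be in 1..40, got {version}")
    if ec_level not in EC_LEVELS:
        raise ValueError(f"EC level must be one of {EC_LEVELS}, got {ec_level!r}")


def data_codewords(version: int, ec_level: str) -> int:
    _check_version_level(version, ec_level)
    _ec, blocks = EC_BLOCKS[(version, ec_level)]
    return sum(n * d for n, d in blocks)


def table_total_codewords(version: int, ec_level: str) -> int:
    ec, blocks = EC_BLOCKS[(version, ec_level)]
    return sum(n * (d + ec) for n, d in blocks)


def size_for_version(version: int) -> int:
    return 17 + 4 * version


def symbol_total_codewords(version: int) -> tuple[int, int]:
    """(total codewords, remainder bits) derived from symbol geometry alone.

    Counts the modules not used by function patterns or format/version
    information; this is independent of :data:`EC_BLOCKS` and is used to
    cross-check the transcribed table.
    """
    size = size_for_version(version)
    total = size * size
    total -= 3 * 64  # finder patterns with separators
    total -= 2 * (size - 16)  # timing patterns between the finders
    total -= 31  # format information (2 x 15) + dark module
    if version >= 7:
        total -= 36  # version information (2 x 18)
    centres = ALIGNMENT_POSITIONS[version]
    if centres:
        k = len(centres)
        n_align = k * k - 3  # corners overlapping finders are skipped
        total -= 25 * n_align
        # alignment patterns centred on a timing line overlap 5 already-counted
        # timing modules each; there are 2*(k-2) such patterns for version >= 7
        overlap = 2 * (k - 2) if k > 2 else 0
        total += 5 * overlap
    return total // 8, total % 8


# ---------------------------------------------------------------------------
# GF(2^8) Reed-Solomon


@lru_cache(maxsize=1)
def _gf_tables() -> tuple[list[int], list[int]]:
    exp = [0] * 512
    log = [0] * 256
    x = 1
    for i in range(255):
        exp[i] = x
        log[x] = i
        x <<= 1
        if x & 0x100:
            x ^= 0x11D
    for i in range(255, 512):
        exp[i] = exp[i - 255]
    return exp, log


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    exp, log = _gf_tables()
    return exp[log[a] + log[b]]


@lru_cache(maxsize=None)
def _rs_generator(degree: int) -> tuple[int, ...]:
    exp, _log = _gf_tables()
    poly = [1]
    for i in range(degree):
        # multiply by (x - alpha^i)
        nxt = [0] * (len(poly) + 1)
        for j, c in enumerate(poly):
            nxt[j] ^= _gf_mul(c, exp[i])
            nxt[j + 1] ^= c
        # poly is kept with highest-degree coefficient last
        poly = nxt
    return tuple(reversed(poly))  # highest degree first


def rs_ec_codewords(data: bytes, degree: int) -> bytes:
    """Reed-Solomon error-correction codewords for one block."""
    gen = _rs_generator(degree)
    rem = list(data) + [0] * degree
    for i in range(len(data)):
        factor = rem[i]
        if factor:
            for j in range(1, len(gen)):
                rem[i + j] ^= _gf_mul(gen[j], factor)
        rem[i] = 0
    return bytes(rem[len(data):])


# ---------------------------------------------------------------------------
# Bit stream and codeword assembly


def byte_mode_bit_length(version: int, n_bytes: int) -> int:
    count_bits = 8 if version <= 9 else 16
    return 4 + count_bits + 8 * n_bytes


def make_codewords(data: bytes, version: int, ec_level: str) -> bytes:
    """Byte-mode segment -> padded data codewords -> interleaved with EC."""
    n_data = data_codewords(version, ec_level)
    if byte_mode_bit_length(version, len(data)) > 8 * n_data:
        raise ValueError(f"data does not fit version {version}-{ec_level}")
    bits: list[int] = []

    def push(value: int, width: int) -> None:
        for shift in range(width - 1, -1, -1):
            bits.append((value >> shift) & 1)

    push(0b0100, 4)
    push(len(data), 8 if version <= 9 else 16)
    for b in data:
        push(b, 8)
    # terminator, pad to byte boundary, then alternating pad codewords
    bits.extend([0] * min(4, 8 * n_data - len(bits)))
    bits.extend([0] * (-len(bits) % 8))
    codewords = bytearray(
        int("".join(map(str, bits[i : i + 8])), 2) for i in range(0, len(bits), 8)
    )
    pads = (0xEC, 0x11)
    i = 0
    while len(codewords) < n_data:
        codewords.append(pads[i % 2])
        i += 1

    ec_per_block, blocks = EC_BLOCKS[(version, ec_level)]
    data_blocks: list[bytes] = []
    pos = 0
    for n_blocks, block_len in blocks:
        for _ in range(n_blocks):
            data_blocks.append(bytes(codewords[pos : pos + block_len]))
            pos += block_len
    ec_blocks = [rs_ec_codewords(b, ec_per_block) for b in data_blocks]

    out = bytearray()
    for i in range(max(len(b) for b in data_blocks)):
        for b in data_blocks:
            if i < len(b):
                out.append(b[i])
    for i in range(ec_per_block):
        for b in ec_blocks:
            out.append(b[i])
    return bytes(out)


# ---------------------------------------------------------------------------
# Matrix construction


def _bch_remainder(value: int, generator: int, gen_bits: int, total_bits: int) -> int:
    rem = value << (gen_bits - 1)
    for shift in range(total_bits - gen_bits, -1, -1):
        if rem & (1 << (shift + gen_bits - 1)):
            rem ^= generator << shift
    return rem


_LEVEL_BITS = {"L": 0b01, "M": 0b00, "Q": 0b11, "H": 0b10}
_FORMAT_MASK = 0b101010000010010


def format_info_bits(ec_level: str, mask: int) -> int:
    data = (_LEVEL_BITS[ec_level] << 3) | mask
    rem = _bch_remainder(data, 0b10100110111, 11, 15)
    return ((data << 10) | rem) ^ _FORMAT_MASK


def version_info_bits(version: int) -> int:
    rem = _bch_remainder(version, 0b1111100100101, 13, 18)
    return (version << 12) | rem


_MASKS = (
    lambda r, c: (r + c) % 2 == 0,
    lambda r, c: r % 2 == 0,
    lambda r, c: c % 3 == 0,
    lambda r, c: (r + c) % 3 == 0,
    lambda r, c: (r // 2 + c // 3) % 2 == 0,
    lambda r, c: (r * c) % 2 + (r * c) % 3 == 0,
    lambda r, c: ((r * c) % 2 + (r * c) % 3) % 2 == 0,
    lambda r, c: ((r + c) % 2 + (r * c) % 3) % 2 == 0,
)


def _base_matrix(version: int) -> tuple[list[list[int | None]], list[list[bool]]]:
    """Function patterns placed; returns (matrix, is_function) with data cells None."""
    size = size_for_version(version)
    m: list[list[int | None]] = [[None] * size for _ in range(size)]
    func = [[False] * size for _ in range(size)]

    def set_module(r: int, c: int, v: int) -> None:
        m[r][c] = v
        func[r][c] = True

    def place_finder(r0: int, c0: int) -> None:
        for r in range(-1, 8):
            for c in range(-1, 8):
                rr, cc = r0 + r, c0 + c
                if not (0 <= rr < size and 0 <= cc < size):
                    continue
                dist = max(abs(r - 3), abs(c - 3))
                set_module(rr, cc, 1 if dist in (0, 1, 3) and 0 <= r <= 6 and 0 <= c <= 6 else 0)

    place_finder(0, 0)
    place_finder(0, size - 7)
    place_finder(size - 7, 0)

    for i in range(8, size - 8):
        v = 1 if i % 2 == 0 else 0
        if not func[6][i]:
            set_module(6, i, v)
        if not func[i][6]:
            set_module(i, 6, v)

    centres = ALIGNMENT_POSITIONS[version]
    for r0 in centres:
        for c0 in centres:
            if func[r0][c0]:  # overlaps a finder corner
                continue
            for r in range(-2, 3):
                for c in range(-2, 3):
                    set_module(r0 + r, c0 + c, 1 if max(abs(r), abs(c)) in (0, 2) else 0)

    # reserve format info areas (values written later)
    for i in range(9):
        if not func[8][i]:
            set_module(8, i, 0)
        if not func[i][8]:
            set_module(i, 8, 0)
    for i in range(8):
        set_module(8, size - 1 - i, 0)
        set_module(size - 1 - i, 8, 0)
    set_module(size - 8, 8, 1)  # dark module

    if version >= 7:
        bits = version_info_bits(version)
        for i in range(18):
            bit = (bits >> i) & 1
            set_module(i // 3, size - 11 + i % 3, bit)
            set_module(size - 11 + i % 3, i // 3, bit)
    return m, func


def _place_data(m: list[list[int | None]], func: list[list[bool]], codewords: bytes) -> None:
    size = len(m)
    bit_iter = (
        (byte >> shift) & 1 for byte in codewords for shift in range(7, -1, -1)
    )
    col = size - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(size - 1, -1, -1) if upward else range(size)
        for r in rows:
            for c in (col, col - 1):
                if not func[r][c]:
                    m[r][c] = next(bit_iter, 0)  # remainder bits are zero
        upward = not upward
        col -= 2


def _apply_mask(m: list[list[int | None]], func: list[list[bool]], mask: int) -> list[list[int]]:
    size = len(m)
    pred = _MASKS[mask]
    out = [[0] * size for _ in range(size)]
    for r in range(size):
        for c in range(size):
            v = m[r][c] or 0
            if not func[r][c] and pred(r, c):
                v ^= 1
            out[r][c] = v
    return out


def _write_format_info(m: list[list[int]], ec_level: str, mask: int) -> None:
    size = len(m)
    bits = format_info_bits(ec_level, mask)
    # bit 14 is most significant; positions per the standard layout
    vals = [(bits >> (14 - i)) & 1 for i in range(15)]
    coords_a = [(8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
                (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8)]
    coords_b = [(size - 1, 8), (size - 2, 8), (size - 3, 8), (size - 4, 8),
                (size - 5, 8), (size - 6, 8), (size - 7, 8),
                (8, size - 8), (8, size - 7), (8, size - 6), (8, size - 5),
                (8, size - 4), (8, size - 3), (8, size - 2), (8, size - 1)]
    for v, (r, c) in zip(vals, coords_a):
        m[r][c] = v
    for v, (r, c) in zip(vals, coords_b):
        m[r][c] = v


def _penalty(m: list[list[int]]) -> int:
    size = len(m)
    score = 0
    # rule 1: runs of >= 5 identical modules
    for line in list(m) + [[m[r][c] for r in range(size)] for c in range(size)]:
        run = 1
        for i in range(1, size):
            if line[i] == line[i - 1]:
                run += 1
            else:
                if run >= 5:
                    score += 3 + run - 5
                run = 1
        if run >= 5:
            score += 3 + run - 5
    # rule 2: 2x2 blocks
    for r in range(size - 1):
        for c in range(size - 1):
            if m[r][c] == m[r][c + 1] == m[r + 1][c] == m[r + 1][c + 1]:
                score += 3
    # rule 3: finder-like pattern with 4-module light margin
    pat1 = [1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0]
    pat2 = pat1[::-1]
    for r in range(size):
        row = m[r]
        col = [m[i][r] for i in range(size)]
        for i in range(size - 10):
            if row[i : i + 11] in (pat1, pat2):
                score += 40
            if col[i : i + 11] in (pat1, pat2):
                score += 40
    # rule 4: dark-module proportion
    dark = sum(sum(row) for row in m)
    pct = dark * 100 // (size * size)
    score += 10 * (abs(pct - 50) // 5)
    return score


def build_matrix(data: bytes, version: int, ec_level: str) -> list[list[int]]:
    """Full masked symbol matrix (1 = dark) for byte-mode data."""
    codewords = make_codewords(data, version, ec_level)
    base, func = _base_matrix(version)
    _place_data(base, func, codewords)
    best = None
    best_score = None
    for mask in range(8):
        cand = _apply_mask(base, func, mask)
        _write_format_info(cand, ec_level, mask)
        score = _penalty(cand)
        if best_score is None or score < best_score:
            best, best_score = cand, score
    assert best is not None
    return best


def smallest_version(n_bytes: int, ec_level: str) -> int | None:
    for version in range(1, 41):
        if byte_mode_bit_length(version, n_bytes) <= 8 * data_codewords(version, ec_level):
            return version
    return None
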