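"""Deterministic LZMA stream compressor used as the built-in generic backend.

Runs as ``python -m pmffrc._xz_backend {c|d} <input> <output>`` so the
optimizer exercises the same child-process machinery (command launch, RSS
polling, exit-status handling) it uses for external reads compressors.
"""

from __future__ import annotations

import lzma
import shutil
import sys

PRESET = 6
CHUNK = 1 << 20


def main(argv: list[str] | None = None) -> int:
    argv = sys.argv[1:] if argv is None else argv
    if len(argv) != 3 or argv[0] not in ("c", "d"):
        print("usage: python -m pmffrc._xz_backend {c|d} <input> <output>", file=sys.stderr)
        return 2
    mode, src, dst = argv
    opener = lzma.open
    if mode == "c":
        with open(src, "rb") as fin, opener(dst, "wb", preset=PRESET) as fout:
            shutil.copyfileobj(fin, fout, CHUNK)
    else:
        with opener(src, "rb") as fin, open(dst, "wb") as fout:
            shutil.copyfileobj(fin, fout, CHUNK)
    return 0


if __name__ == "__main__":
    sys.exit(main())
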