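"""Package-wide logging helper."""

from __future__ import annotations

import logging
import sys

_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"


def get_logger(name: str) -> logging.Logger:
    return logging.getLogger(f"mrgradient.{name}")


def configure(level: str = "INFO") -> None:
    """Configure the root package logger (used by the CLI)."""
    root = logging.getLogger("mrgradient")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_FORMAT))
        root.addHandler(handler)
    root.setLevel(level.upper())
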