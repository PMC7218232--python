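"""Shared helpers: seed substreams, GMT I/O, small validation utilities."""

from __future__ import annotations

import zlib

import numpy as np


class ConfigError(ValueError):
    """Raised when a configuration value is invalid."""


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from a global seed.

    Keyed by the stage name so inserting a stage does not perturb the
    randomness of the others. Result is < 2**31.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")
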