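"""Shared helpers: seeded RNG streams and GTDB-style lineage handling."""

from __future__ import annotations

import numpy as np

#: Rank prefixes in a GTDB lineage string, outermost first.
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = {
    "domain": "d__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent generators from one root seed.

    A single root seed drives every stochastic step; each operation gets
    its own child stream so that adding a step never perturbs the draws
    of another.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def child_seed(seed: int, index: int) -> int:
    """A derived integer seed (< 2**31), stable in ``seed`` and ``index``."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a ``d__...;p__...;...;s__...`` lineage string into ranks.

    Raises ``ValueError`` for strings that do not follow the convention.
    """
    parts = [p.strip() for p in lineage.split(";")]
    out: dict[str, str] = {}
    for part in parts:
        for rank, prefix in _RANK_PREFIX.items():
            if part.startswith(prefix):
                out[rank] = part[len(prefix):]
                break
        else:
            raise ValueError(f"malformed lineage component {part!r} in {lineage!r}")
    if "phylum" not in out:
        raise ValueError(f"lineage lacks a phylum component: {lineage!r}")
    return out


def lineage_taxon(lineage: str, level: str) -> str:
    """The taxon name at ``level`` ('phylum', 'family', 'species', ...)."""
    ranks = parse_lineage(lineage)
    if level not in ranks:
        raise ValueError(f"lineage {lineage!r} has no rank {level!r}")
    return ranks[level]


def make_lineage(**ranks: str) -> str:
    """Assemble a GTDB-style lineage string from rank names."""
    return ";".join(_RANK_PREFIX[r] + ranks.get(r, "") for r in LINEAGE_RANKS)
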