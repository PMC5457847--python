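"""Cross-species comparison of differentially expressed miRNAs.

Mature miRNA names are matched lexically: the three-letter species prefix
(hsa-, rno-, mmu-, ...) is stripped, the name lowercased, and the -5p/-3p
arm suffix preserved verbatim, so ``hsa-miR-182`` and ``rno-miR-182`` share
the family key ``mir-182``.  No ortholog database is consulted.  Arm
suffixes must match exactly by default; ``collapse_arms`` relaxes this.
"""

from __future__ import annotations

import re
from typing import NamedTuple

import pandas as pd

from .errors import ConfigError

_PREFIX_RE = re.compile(r"^([a-z]{3})-(?=(mir|let)\b|mir|let)")
_ARM_RE = re.compile(r"-(5p|3p)$")


class MirnaKey(NamedTuple):
    key: str
    original: str


def normalize_mirna_name(name: str, *, collapse_arms: bool = False) -> MirnaKey:
    """Species-prefix-insensitive family key for a mature miRNA id.

    Idempotent: normalizing a key returns the same key.
    """
    if not name or not str(name).strip():
        raise ConfigError("empty miRNA identifier")
    key = str(name).strip().lower()
    key = _PREFIX_RE.sub("", key, count=1)
    if collapse_arms:
        key = _ARM_RE.sub("", key)
    return MirnaKey(key=key, original=str(name))


def shared_demirs(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    *,
    collapse_arms: bool = False,
    suffixes: tuple[str, str] = ("_a", "_b"),
) -> pd.DataFrame:
    """Join two DE-miRNA tables on the normalized family key.

    Each input must be indexed by miRNA id and carry a ``direction`` column.
    Returns one row per shared family with per-species ids and directions
    and a ``concordant`` flag (same direction in both species).
    """
    def keyed(table: pd.DataFrame, suffix: str) -> pd.DataFrame:
        rows = [
            {
                "key": normalize_mirna_name(str(i), collapse_arms=collapse_arms).key,
                f"id{suffix}": str(i),
                f"direction{suffix}": d,
            }
            for i, d in table["direction"].items()
        ]
        out = pd.DataFrame(rows, columns=["key", f"id{suffix}", f"direction{suffix}"])
        return out.drop_duplicates(subset="key", keep="first")

    sa, sb = suffixes
    merged = keyed(table_a, sa).merge(keyed(table_b, sb), on="key", how="inner")
    merged["concordant"] = merged[f"direction{sa}"] == merged[f"direction{sb}"]
    return merged.sort_values("key").reset_index(drop=True)
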