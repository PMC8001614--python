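"""Residue-type composition of a residue set and its polarity breakdown."""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .constants import POLARITY_SCHEMES, STANDARD_AA
from .errors import ConfigurationError
from .structure import ResidueKey, StructureModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PolarityScheme:
    """Partition of the 20 standard residue types into charged /
    polar-uncharged / non-polar classes."""

    name: str
    charged: frozenset[str]
    polar_uncharged: frozenset[str]
    nonpolar: frozenset[str]

    def __post_init__(self):
        union = self.charged | self.polar_uncharged | self.nonpolar
        total = len(self.charged) + len(self.polar_uncharged) + len(self.nonpolar)
        if union != STANDARD_AA or total != 20:
            raise ConfigurationError(
                f"polarity scheme {self.name!r} does not partition the 20 standard types"
            )

    @classmethod
    def named(cls, name: str) -> "PolarityScheme":
        if name not in POLARITY_SCHEMES:
            raise ConfigurationError(
                f"unknown polarity scheme {name!r}; have {sorted(POLARITY_SCHEMES)}"
            )
        s = POLARITY_SCHEMES[name]
        return cls(name=name, **s)


DEFAULT_SCHEME = PolarityScheme.named("default")


@dataclass
class CompositionSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    polar_fraction: float
    charged_fraction: float
    nonpolar_fraction: float
    ranking: list[str] = field(default_factory=list)
    n_total: int = 0
    scheme: str = "default"

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "counts": self.counts,
            "fractions": self.fractions,
            "polar_fraction": self.polar_fraction,
            "charged_fraction": self.charged_fraction,
            "nonpolar_fraction": self.nonpolar_fraction,
            "ranking": self.ranking,
            "scheme": self.scheme,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        lines = ["res_type\tcount\tfraction"]
        for rt in self.ranking:
            lines.append(f"{rt}\t{self.counts[rt]}\t{self.fractions[rt]:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def composition(
    residues: Iterable[ResidueKey],
    model: StructureModel,
    scheme: PolarityScheme = DEFAULT_SCHEME,
) -> CompositionSummary:
    """Tally residue types over a residue-key set and classify polarity.

    Non-standard residues are excluded with a warning; an empty input yields a
    zero-count summary (not an error). Ranking is by count descending, ties
    alphabetical.
    """
    counter: Counter[str] = Counter()
    for key in residues:
        res = model.get_residue(key)
        if not res.is_standard:
            logger.warning("residue %s type %s is non-standard; excluded from composition", key, res.res_type)
            continue
        counter[res.res_type] += 1
    n = sum(counter.values())
    counts = dict(counter)
    fractions = {rt: c / n for rt, c in counts.items()} if n else {}
    charged = sum(c for rt, c in counts.items() if rt in scheme.charged)
    polar_unc = sum(c for rt, c in counts.items() if rt in scheme.polar_uncharged)
    nonpolar = sum(c for rt, c in counts.items() if rt in scheme.nonpolar)
    ranking = sorted(counts, key=lambda rt: (-counts[rt], rt))
    return CompositionSummary(
        counts=counts,
        fractions=fractions,
        polar_fraction=(charged + polar_unc) / n if n else 0.0,
        charged_fraction=charged / n if n else 0.0,
        nonpolar_fraction=nonpolar / n if n else 0.0,
        ranking=ranking,
        n_total=n,
        scheme=scheme.name,
    )
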