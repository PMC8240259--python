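"""Curated marker-gene lists (integrase Pfams, metal-resistance KOs).

Lysogeny calling and metal-resistance-gene (MRG) screening are driven by
identifier lists rather than by sequence search: a viral contig is flagged
lysogenic when at least one of its genes hits a phage-integrase Pfam
family, and MRGs are recognised by KEGG orthology (KO) identifiers for
heavy-metal membrane transporters and reductases.

The default lists shipped here are small, plausible placeholders intended
for synthetic benchmarks and demonstration runs.  For real data, users
should load their own curated lists with :meth:`MarkerGeneList.from_tsv`
(two tab-separated columns: ``namespace`` and ``id``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigError

VALID_NAMESPACES = ("pfam", "ko")


@dataclass(frozen=True)
class MarkerGeneList:
    """A named set of marker identifiers in a single annotation namespace."""

    name: str
    namespace: str
    identifiers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.namespace not in VALID_NAMESPACES:
            raise ConfigError(
                f"namespace must be one of {VALID_NAMESPACES}, got {self.namespace!r}"
            )
        if not self.identifiers:
            raise ConfigError(f"marker list {self.name!r} is empty")
        object.__setattr__(self, "identifiers", frozenset(self.identifiers))

    def __contains__(self, identifier: object) -> bool:
        return identifier in self.identifiers

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "MarkerGeneList":
        """Load a marker list from a two-column TSV (namespace, id)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"namespace", "id"}.issubset(df.columns):
            raise ConfigError(f"{path}: expected columns 'namespace' and 'id'")
        namespaces = set(df["namespace"].unique())
        if len(namespaces) != 1:
            raise ConfigError(f"{path}: mixed namespaces {sorted(namespaces)}")
        return cls(
            name=name or Path(path).stem,
            namespace=namespaces.pop(),
            identifiers=frozenset(df["id"]),
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"namespace": self.namespace, "id": sorted(self.identifiers)}
        ).to_csv(path, sep="\t", index=False)


# Phage integrase family Pfams (tyrosine/serine recombinases and relatives).
DEFAULT_INTEGRASE_PFAMS = MarkerGeneList(
    name="integrase",
    namespace="pfam",
    identifiers=frozenset(
        {"PF00589", "PF00239", "PF02899", "PF07508", "PF09003", "PF13495"}
    ),
)

# Heavy-metal membrane transporter KOs (efflux pumps and ABC transporters).
DEFAULT_TRANSPORTER_KOS = MarkerGeneList(
    name="transporter",
    namespace="ko",
    identifiers=frozenset(
        {"K15726", "K16264", "K07787", "K17686", "K07798", "K01551"}
    ),
)

# Heavy-metal reductase KOs (e.g. chromate and arsenate reductases).
DEFAULT_REDUCTASE_KOS = MarkerGeneList(
    name="reductase",
    namespace="ko",
    identifiers=frozenset({"K00537", "K19784", "K00362", "K18881"}),
)
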