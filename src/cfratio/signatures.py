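"""Gene signatures for tumor-microenvironment scoring.

Signatures are ordered lists of gene symbols with a provenance tag.  The
built-in registry ships 24 immune-cell-type signatures, the 8-gene
cancer-associated-fibroblast (CAF) panel of the Microenvironment Cell
Populations counter (COL1A1, COL3A1, COL6A1, COL6A2, DCN, GREM1, PAMR1,
TAGLN), and a CD8 T-cell list kept verbatim apart from removal of exact
duplicates.  Legacy symbols in the CD8 list (C4orf15, MYST3, SFRS7, ...)
are deliberately NOT modernized: scoring is exact identifier matching
against the user's matrix, and silent symbol updating would change scores
irreproducibly.  Users who need alias handling supply their own mapping
table before scoring.

Gene-symbol matching throughout the package is case-sensitive exact match.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from cfratio._synthetic_bindea_standins import SYNTHETIC_IMMUNE_MARKERS

logger = logging.getLogger(__name__)

# Printed CD8 T-cell marker list, verbatim order; DNAJB1 and ZFP36L2 appear
# twice in the source and are collapsed by first occurrence.
_CD8_T_CELL_GENES = [
    "DNAJB1", "DNAJB1", "ZFP36L2", "ZFP36L2", "VAMP2", "PPP1R2", "TBCC",
    "LEPROTL1", "CAMLG", "KLF9", "GADD45A", "CD8A", "ZNF91", "PF4",
    "THUMPD1", "TSC22D3", "SLC16A7", "GZMM", "ZEB1", "RBM3", "APBA2",
    "C4orf15", "SF1", "FLT3LG", "C19orf6", "ZNF609", "SFRS7", "PRF1",
    "TMC6", "MYST3", "AES", "ZNF22", "ABT1", "CDKN2AIP", "ARHGAP8",
    "LIME1", "PRR5", "C12orf47",
]

_CAF_GENES = ["COL1A1", "COL3A1", "COL6A1", "COL6A2", "DCN", "GREM1", "PAMR1", "TAGLN"]

#: The 24 immune cell types of the built-in registry (innate + adaptive).
IMMUNE_CELL_TYPES = (
    "NK cells", "NK CD56dim cells", "NK CD56bright cells", "DC", "pDC",
    "iDC", "aDC", "Neutrophils", "Mast cells", "Eosinophils", "Macrophages",
    "B cells", "T cells", "CD8 T cells", "T helper cells", "Th1", "Th2",
    "Th17", "Tgd", "Tcm", "Tem", "TFH", "Treg", "Cytotoxic cells",
)


def _dedup(genes: list[str]) -> list[str]:
    """Drop duplicate symbols, keeping first occurrence order."""
    seen: set[str] = set()
    out = []
    for g in genes:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene list with a provenance tag.

    Duplicate symbols are collapsed at construction (first occurrence
    wins); empty names, empty gene lists and empty symbols are rejected.
    """

    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __init__(self, name: str, genes, source: str = ""):
        if not name:
            raise ValueError("signature name must be non-empty")
        genes = list(genes)
        if any(g == "" for g in genes):
            raise ValueError(f"signature {name!r}: empty gene symbol")
        deduped = _dedup(genes)
        if not deduped:
            raise ValueError(f"signature {name!r}: no genes after deduplication")
        if len(deduped) < len(genes):
            logger.warning(
                "signature %r: %d duplicate gene symbol(s) collapsed",
                name, len(genes) - len(deduped),
            )
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", tuple(deduped))
        object.__setattr__(self, "source", source)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SignatureRegistry:
    """An ordered mapping of unique signature names to :class:`GeneSignature`."""

    signatures: dict[str, GeneSignature] = field(default_factory=dict)

    def add(self, sig: GeneSignature) -> None:
        if sig.name in self.signatures:
            raise ValueError(f"duplicate signature name {sig.name!r}")
        self.signatures[sig.name] = sig

    def __getitem__(self, name: str) -> GeneSignature:
        return self.signatures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.signatures

    def __iter__(self):
        return iter(self.signatures.values())

    def __len__(self) -> int:
        return len(self.signatures)

    @property
    def names(self) -> list[str]:
        return list(self.signatures)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignatureRegistry):
            return NotImplemented
        return self.signatures == other.signatures

    def union_signature(self, name: str, members: list[str] | None = None) -> GeneSignature:
        """Union of member signatures' genes (first-occurrence order).

        Default members are all signatures in the registry.  Used to build
        the composite immune meta-signature.
        """
        members = self.names if members is None else members
        genes: list[str] = []
        for m in members:
            genes.extend(self[m].genes)
        return GeneSignature(name, genes, source=f"union of {len(members)} signatures")

    def to_json(self) -> str:
        """Serialize for reporting (name, source, genes)."""
        return json.dumps(
            [{"name": s.name, "source": s.source, "genes": list(s.genes)} for s in self],
            indent=2,
        )


def load_gmt(path) -> SignatureRegistry:
    """Parse a GMT file (one set per line: name, description, genes...).

    Duplicate genes within a line are collapsed with a warning; a
    duplicate set name or a line with fewer than three fields is an error
    naming the offending line.  An empty file yields an empty registry.
    """
    reg = SignatureRegistry()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g != ""]
            try:
                sig = GeneSignature(name, genes, source=desc)
                reg.add(sig)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return reg


def write_gmt(reg: SignatureRegistry, path) -> None:
    """Write a registry as GMT; round-trips through :func:`load_gmt`."""
    with open(path, "w") as fh:
        for sig in reg:
            fh.write("\t".join([sig.name, sig.source or "na", *sig.genes]) + "\n")


def builtin_registry() -> SignatureRegistry:
    """The shipped registry: 24 immune cell types plus the CAF panel.

    The CD8 T-cell and CAF lists are the authentic published panels; the
    other 23 immune lists are synthetic curated stand-ins (see
    ``_synthetic_bindea_standins``) and should be replaced via
    :func:`load_gmt` when reproducing published scores.  Each call returns
    a fresh, equal registry.
    """
    reg = SignatureRegistry()
    for cell_type in IMMUNE_CELL_TYPES:
        if cell_type == "CD8 T cells":
            reg.add(GeneSignature(cell_type, _CD8_T_CELL_GENES, source="published CD8 marker list"))
        else:
            reg.add(GeneSignature(cell_type, SYNTHETIC_IMMUNE_MARKERS[cell_type],
                                  source="synthetic curated stand-in"))
    reg.add(GeneSignature("CAF", _CAF_GENES, source="MCP-counter fibroblast panel"))
    return reg
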