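"""Immune gene signatures and mutually exclusive signature families.

Polarization of T helper cells (Th1/Th2/Th17/iTreg) and of tumor-associated
macrophages (M1/M2) is treated as a mutually exclusive process: a sample's
polarization bias is scored against the genes that are unique to each subset
within its family.  This module encodes the packaged immune gene panel,
loads/saves panel definition files, and performs the mutual-exclusivity
reduction.

Gene symbols are canonicalized by upper-casing and mapping ``.`` to ``-`` so
that R-style exports (``HLA.DRA``) and HUGO symbols (``HLA-DRA``) match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger("immunopolar")

__all__ = [
    "GeneSignature",
    "SignatureFamily",
    "PanelError",
    "canonical_symbol",
    "load_panel",
    "save_panel",
    "default_panel",
    "thelper_family",
    "macrophage_family",
    "infiltration_markers",
    "revised_th2_family",
    "reduce_to_exclusive",
    "restrict_to_genes",
    "panel_gene_union",
]

_DEFAULT_PANEL_RESOURCE = "default_panel.yaml"

#: Families whose subsets enter the polarization likelihood.
POLARIZATION_FAMILIES = ("Thelper", "macrophage")


class PanelError(ValueError):
    """Malformed or degenerate gene-panel definition."""


def canonical_symbol(symbol: str) -> str:
    """Return the canonical form of a gene symbol (upper case, ``.`` -> ``-``)."""
    return str(symbol).strip().upper().replace(".", "-")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set defining one polarization subset (or marker group)."""

    name: str
    genes: tuple[str, ...]
    family: str = "other"

    def __post_init__(self) -> None:
        canon = tuple(canonical_symbol(g) for g in self.genes)
        if not canon:
            raise PanelError(f"signature {self.name!r}: gene list is empty")
        if len(set(canon)) != len(canon):
            dupes = sorted({g for g in canon if canon.count(g) > 1})
            raise PanelError(f"signature {self.name!r}: duplicate symbols {dupes}")
        object.__setattr__(self, "genes", canon)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class SignatureFamily:
    """K >= 2 subsets of one cell type plus their mutually exclusive reduction.

    ``exclusive`` maps each subset name to its genes after removing any gene
    that appears in another subset of the same family; it is ``None`` until
    :func:`reduce_to_exclusive` is applied.
    """

    label: str
    subsets: tuple[GeneSignature, ...]
    exclusive: Mapping[str, tuple[str, ...]] | None = field(default=None)

    def __post_init__(self) -> None:
        names = [s.name for s in self.subsets]
        if len(set(names)) != len(names):
            raise PanelError(f"family {self.label!r}: duplicate subset names")
        if self.exclusive is not None:
            excl = {k: tuple(v) for k, v in self.exclusive.items()}
            if set(excl) != set(names):
                raise PanelError(
                    f"family {self.label!r}: exclusive mapping does not cover subsets"
                )
            flat = [g for genes in excl.values() for g in genes]
            if len(set(flat)) != len(flat):
                raise PanelError(f"family {self.label!r}: exclusive sets overlap")
            object.__setattr__(self, "exclusive", excl)

    @property
    def k(self) -> int:
        """Number of polarization subsets (the number of competing models)."""
        return len(self.subsets)

    @property
    def subset_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.subsets)

    def subset(self, name: str) -> GeneSignature:
        for s in self.subsets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def genes(self) -> tuple[str, ...]:
        """Union of all subset genes, first-seen order."""
        seen: dict[str, None] = {}
        for s in self.subsets:
            for g in s.genes:
                seen.setdefault(g)
        return tuple(seen)


def reduce_to_exclusive(family: SignatureFamily) -> SignatureFamily:
    """Remove genes shared between subsets; each subset keeps its unique genes.

    Raises :class:`PanelError` (naming the subset) if any subset loses all of
    its genes, since an empty model cannot be scored.
    """
    if family.k < 2:
        raise PanelError(f"family {family.label!r}: need >= 2 subsets to reduce")
    exclusive: dict[str, tuple[str, ...]] = {}
    for s in family.subsets:
        others: set[str] = set()
        for t in family.subsets:
            if t.name != s.name:
                others |= t.gene_set
        kept = tuple(g for g in s.genes if g not in others)
        if not kept:
            raise PanelError(
                f"family {family.label!r}: subset {s.name!r} has no exclusive genes"
            )
        exclusive[s.name] = kept
    return replace(family, exclusive=exclusive)


def _family_from_mapping(label: str, mapping: Mapping[str, Iterable[str]]) -> SignatureFamily:
    subsets = []
    for name, genes in mapping.items():
        genes = list(genes) if genes is not None else []
        if not genes:
            raise PanelError(f"family {label!r}, subset {name!r}: empty gene list")
        subsets.append(GeneSignature(name=str(name), genes=tuple(genes), family=label))
    return SignatureFamily(label=label, subsets=tuple(subsets))


def load_panel(path: str | Path | None = None) -> list[SignatureFamily]:
    """Load signature families from a panel definition file.

    The file is a YAML mapping ``{family: {subset: [SYMBOL, ...]}}``.  With no
    ``path`` the packaged default panel (the published immune gene table) is
    loaded.
    """
    if path is None:
        text = (
            resources.files("immunopolar").joinpath("data", _DEFAULT_PANEL_RESOURCE).read_text()
        )
    else:
        text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - yaml reports position
        raise PanelError(f"cannot parse panel file: {exc}") from exc
    if not isinstance(raw, dict):
        raise PanelError("panel file must be a mapping {family: {subset: [genes]}}")
    families = []
    for label, mapping in raw.items():
        if not isinstance(mapping, dict):
            raise PanelError(f"family {label!r}: expected a mapping of subsets")
        families.append(_family_from_mapping(str(label), mapping))
    return families


def save_panel(families: Iterable[SignatureFamily], path: str | Path) -> None:
    """Write families to the canonical YAML panel format (round-trip stable)."""
    doc = {f.label: {s.name: list(s.genes) for s in f.subsets} for f in families}
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)
    )


def default_panel() -> list[SignatureFamily]:
    """The packaged immune gene panel (T-helper, macrophage, infiltration, other)."""
    return load_panel(None)


def _get_family(label: str, families: Iterable[SignatureFamily] | None = None) -> SignatureFamily:
    for f in families if families is not None else default_panel():
        if f.label == label:
            return f
    raise KeyError(label)


def thelper_family(reduced: bool = True) -> SignatureFamily:
    """The four-subset T-helper family (Th1/Th2/Th17/iTreg)."""
    fam = _get_family("Thelper")
    return reduce_to_exclusive(fam) if reduced else fam


def macrophage_family(reduced: bool = True) -> SignatureFamily:
    """The two-subset tumor-associated macrophage family (M1/M2)."""
    fam = _get_family("macrophage")
    return reduce_to_exclusive(fam) if reduced else fam


def infiltration_markers() -> SignatureFamily:
    """NK, T cell and macrophage recruitment marker sets (not reduced)."""
    return _get_family("infiltration")


def revised_th2_family(reduced: bool = False) -> SignatureFamily:
    """T-helper family with the revised five-gene Th2 signature.

    The revised Th2 signature drops PPARG and IL6 (whose product can repress
    type 2 cytokine transcription), leaving {CD4, IL4, IL5, IL10, GATA3}.
    """
    fam = thelper_family(reduced=False)
    subsets = tuple(
        GeneSignature("Th2", ("CD4", "IL4", "IL5", "IL10", "GATA3"), fam.label)
        if s.name == "Th2"
        else s
        for s in fam.subsets
    )
    revised = SignatureFamily(label=fam.label, subsets=subsets)
    return reduce_to_exclusive(revised) if reduced else revised


def restrict_to_genes(
    family: SignatureFamily, available: Iterable[str]
) -> SignatureFamily:
    """Drop genes missing from ``available``; error if a subset empties.

    Platform coverage varies, so genes absent from an input matrix are removed
    from the working signature with a warning rather than failing, provided at
    least one gene per subset survives.  Any existing exclusive reduction is
    recomputed on the surviving genes.
    """
    avail = {canonical_symbol(g) for g in available}
    subsets = []
    for s in family.subsets:
        kept = tuple(g for g in s.genes if g in avail)
        dropped = [g for g in s.genes if g not in avail]
        if dropped:
            logger.warning(
                "family %s subset %s: dropping genes absent from matrix: %s",
                family.label, s.name, ", ".join(dropped),
            )
        if not kept:
            raise PanelError(
                f"family {family.label!r}: subset {s.name!r} has no genes in matrix"
            )
        subsets.append(GeneSignature(s.name, kept, s.family))
    out = SignatureFamily(label=family.label, subsets=tuple(subsets))
    return reduce_to_exclusive(out) if family.exclusive is not None else out


def panel_gene_union(families: Iterable[SignatureFamily] | None = None) -> tuple[str, ...]:
    """Sorted union of all genes in the panel (the full published gene table)."""
    fams = list(families) if families is not None else default_panel()
    genes: set[str] = set()
    for f in fams:
        genes.update(f.genes)
    return tuple(sorted(genes))
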