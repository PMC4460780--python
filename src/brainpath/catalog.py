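"""Brain-pathway catalog: definitions, lateralization expansion, edge lists.

A *brain pathway* is a curated set of anatomically separate but functionally
connected regions, encoded as an ordered region sequence whose consecutive
pairs are its connectivities (edges).  Catalog rows are hemisphere-neutral
definitions; :func:`expand_lateralization` realizes them as concrete
:class:`PathwayInstance` objects over a parcellation's label set — bilateral
rows become a left and a right instance, unilateral rows one instance, and
the ``special`` default-mode-network row becomes its two named variants
(PCC and vmPFC).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CatalogError",
    "ParcellationLabels",
    "PathwayDefinition",
    "PathwayInstance",
    "aal116_labels",
    "bundled_catalog_path",
    "edges_from_sequence",
    "expand_lateralization",
    "load_catalog",
    "load_labels",
    "write_catalog",
]

DOMAINS = frozenset({"cognition", "emotion", "motor", "sensation", "recognition"})
LATERALIZATIONS = frozenset({"left", "right", "bilateral", "special"})

#: hemisphere suffixes appended to neutral region names at expansion (AAL style)
HEMI_SUFFIX = {"left": "_L", "right": "_R"}


class CatalogError(ValueError):
    """Raised for malformed catalogs, unresolvable regions, or bad sequences."""


@dataclass(frozen=True)
class ParcellationLabels:
    """Ordered region names of a parcellation; position defines the 0-based index."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise CatalogError("parcellation labels must be unique")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index  # type: ignore[attr-defined]

    def index(self, name: str) -> int:
        try:
            return self._index[name]  # type: ignore[attr-defined]
        except KeyError:
            raise CatalogError(f"region {name!r} not in parcellation") from None

    @property
    def n_pairs(self) -> int:
        """Number of distinct unordered region pairs, N(N-1)/2."""
        n = len(self.names)
        return n * (n - 1) // 2


@dataclass(frozen=True)
class PathwayDefinition:
    """One catalog row: a named pathway before lateralization expansion.

    ``region_sequence`` holds hemisphere-neutral names for left/right/bilateral
    rows and is empty for ``special`` rows, whose concrete per-variant
    sequences live in ``variants`` (variant name -> explicit region names).
    """

    name: str
    domain: str
    function: str
    lateralization: str
    closed: bool
    region_sequence: tuple[str, ...] = ()
    variants: tuple[tuple[str, tuple[str, ...]], ...] = ()
    reference: str = ""

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise CatalogError(f"{self.name}: unknown behavioral domain {self.domain!r}")
        if self.lateralization not in LATERALIZATIONS:
            raise CatalogError(
                f"{self.name}: unknown lateralization {self.lateralization!r}"
            )
        if self.lateralization == "special":
            if not self.variants:
                raise CatalogError(f"{self.name}: special row requires named variants")
            for vname, seq in self.variants:
                if len(seq) < 2:
                    raise CatalogError(
                        f"{self.name}/{vname}: region sequence needs >= 2 regions"
                    )
        elif len(self.region_sequence) < 2:
            raise CatalogError(f"{self.name}: region sequence needs >= 2 regions")


@dataclass(frozen=True)
class PathwayInstance:
    """A lateralized pathway realized as an ordered edge list over atlas regions."""

    id: str
    edges: tuple[tuple[str, str], ...]
    definition: PathwayDefinition | None = field(default=None, compare=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_names(self) -> tuple[str, ...]:
        return tuple(f"{a}--{b}" for a, b in self.edges)


def edges_from_sequence(
    sequence: Sequence[str], closed: bool = False
) -> tuple[tuple[str, str], ...]:
    """Consecutive region pairs of an ordered sequence, plus the closing pair.

    Edges are unordered pairs stored in traversal orientation.  A repeated
    unordered pair is an error: each edge contributes exactly one correlation
    value, so a pathway may revisit regions but not re-use an edge.
    """
    if len(sequence) < 2:
        raise CatalogError("region sequence needs >= 2 regions")
    pairs = list(zip(sequence[:-1], sequence[1:]))
    if closed:
        pairs.append((sequence[-1], sequence[0]))
    seen: set[frozenset[str]] = set()
    for a, b in pairs:
        if a == b:
            raise CatalogError(f"self-pair on region {a!r}")
        key = frozenset((a, b))
        if key in seen:
            raise CatalogError(f"duplicate edge between {a!r} and {b!r}")
        seen.add(key)
    return tuple(pairs)


def _resolve(name: str, labels: ParcellationLabels, context: str) -> None:
    if name not in labels:
        raise CatalogError(f"{context}: region {name!r} not found in parcellation")


def _validate_definition(defn: PathwayDefinition, labels: ParcellationLabels) -> None:
    if defn.lateralization == "special":
        for vname, seq in defn.variants:
            for region in seq:
                _resolve(region, labels, f"{defn.name}/{vname}")
            edges_from_sequence(seq, defn.closed)
        return
    sides = ("left", "right") if defn.lateralization == "bilateral" else (defn.lateralization,)
    for side in sides:
        suffix = HEMI_SUFFIX[side]
        for region in defn.region_sequence:
            _resolve(region + suffix, labels, defn.name)
    edges_from_sequence(defn.region_sequence, defn.closed)


def expand_lateralization(
    definitions: Iterable[PathwayDefinition],
) -> list[PathwayInstance]:
    """Expand catalog definitions into concrete lateralized pathway instances.

    Bilateral rows yield a left and a right instance (region names suffixed
    ``_L`` / ``_R``), unilateral rows one instance, and special rows one
    instance per named variant.  Expansion is deterministic: the same
    definitions always produce the same ids and edges, and instances
    themselves cannot be re-expanded.
    """
    instances: list[PathwayInstance] = []
    for defn in definitions:
        if not isinstance(defn, PathwayDefinition):
            raise TypeError(
                f"expected PathwayDefinition, got {type(defn).__name__}; "
                "pathway instances cannot be re-expanded"
            )
        if defn.lateralization == "special":
            for vname, seq in defn.variants:
                instances.append(
                    PathwayInstance(
                        id=f"{defn.name} ({vname})",
                        edges=edges_from_sequence(seq, defn.closed),
                        definition=defn,
                    )
                )
            continue
        sides = (
            ("left", "right") if defn.lateralization == "bilateral" else (defn.lateralization,)
        )
        for side in sides:
            suffix = HEMI_SUFFIX[side]
            seq = tuple(r + suffix for r in defn.region_sequence)
            instances.append(
                PathwayInstance(
                    id=f"{defn.name} ({side[0].upper()})",
                    edges=edges_from_sequence(seq, defn.closed),
                    definition=defn,
                )
            )
    ids = [inst.id for inst in instances]
    if len(set(ids)) != len(ids):
        raise CatalogError("duplicate pathway instance ids after expansion")
    return instances


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(text: str, context: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise CatalogError(f"{context}: bad closed flag {text!r}")


def _parse_regions(
    text: str, lateralization: str, context: str
) -> tuple[tuple[str, ...], tuple[tuple[str, tuple[str, ...]], ...]]:
    if lateralization == "special":
        variants = []
        for chunk in text.split("|"):
            if ":" not in chunk:
                raise CatalogError(f"{context}: special row variant missing 'name:' prefix")
            vname, seq = chunk.split(":", 1)
            variants.append(
                (vname.strip(), tuple(s.strip() for s in seq.split(";") if s.strip()))
            )
        return (), tuple(variants)
    return tuple(s.strip() for s in text.split(";") if s.strip()), ()


_COLUMNS = ["name", "domain", "function", "lateralization", "closed", "regions", "reference"]


def load_catalog(path: str | Path, labels: ParcellationLabels) -> list[PathwayDefinition]:
    """Load and validate a TSV pathway catalog against a parcellation.

    The file has a header row with columns ``name, domain, function,
    lateralization, closed, regions, reference``; ``#`` lines are comments.
    Validation errors name the offending row and region.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        return []
    reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter="\t")
    if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _COLUMNS:
        raise CatalogError(
            f"catalog header must be {_COLUMNS}, got {reader.fieldnames}"
        )
    definitions: list[PathwayDefinition] = []
    seen_names: set[str] = set()
    for row_no, row in enumerate(reader, start=2):
        name = (row["name"] or "").strip()
        context = f"catalog row {row_no} ({name or 'unnamed'})"
        if not name:
            raise CatalogError(f"{context}: missing pathway name")
        if name in seen_names:
            raise CatalogError(f"{context}: duplicate pathway id {name!r}")
        seen_names.add(name)
        lateralization = (row["lateralization"] or "").strip().lower()
        sequence, variants = _parse_regions(row["regions"] or "", lateralization, context)
        try:
            defn = PathwayDefinition(
                name=name,
                domain=(row["domain"] or "").strip().lower(),
                function=(row["function"] or "").strip(),
                lateralization=lateralization,
                closed=_parse_bool(row["closed"] or "", context),
                region_sequence=sequence,
                variants=variants,
                reference=(row["reference"] or "").strip(),
            )
            _validate_definition(defn, labels)
        except CatalogError as err:
            raise CatalogError(f"{context}: {err}") from None
        definitions.append(defn)
    return definitions


def write_catalog(definitions: Iterable[PathwayDefinition], path: str | Path) -> None:
    """Write definitions in the TSV catalog format (round-trips with load_catalog)."""
    rows = ["\t".join(_COLUMNS)]
    for d in definitions:
        if d.lateralization == "special":
            regions = "|".join(f"{v}:{';'.join(seq)}" for v, seq in d.variants)
        else:
            regions = ";".join(d.region_sequence)
        rows.append(
            "\t".join(
                [
                    d.name,
                    d.domain,
                    d.function,
                    d.lateralization,
                    "true" if d.closed else "false",
                    regions,
                    d.reference,
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


def load_labels(path: str | Path) -> ParcellationLabels:
    """Read parcellation labels, one region name per line (``#`` = comment)."""
    names = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    return ParcellationLabels(tuple(names))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("brainpath").joinpath("data", name)))


def aal116_labels() -> ParcellationLabels:
    """The bundled AAL-116 parcellation label set."""
    labels = load_labels(_data_path("aal116_labels.txt"))
    if len(labels) != 116:
        raise CatalogError("bundled AAL label file is corrupt")
    return labels


def bundled_catalog_path() -> Path:
    """Path of the bundled 33-row pathway catalog over AAL-116."""
    return _data_path("pathways_aal116.tsv")
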