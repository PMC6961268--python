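"""Barcode codebook: the mapping from short in situ sequencing barcodes to targets.

Each padlock probe carries a barcode of fixed length L (one base read per
sequencing-by-ligation cycle, L = 4 in the original assay design).  Editing
sites are interrogated by a *pair* of probes that differ in the base at the
editing position, so every ``site_id`` must appear exactly twice in a valid
codebook: once as ``edited_variant`` and once as ``unedited_variant``.
Marker probes additionally carry the cell class they report (interneuron,
pyramidal, oligodendrocyte, astrocyte, ...), and probes of the ADAR enzyme
family carry a ``transcript_group`` (several probes tile one transcript but
share a single barcode per target).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

#: Barcode alphabet; index in this string is the image channel carrying that base.
ALPHABET = "ACGT"

#: Sentinel returned for barcodes not present in the codebook.
UNMATCHED = "UNMATCHED"

PROBE_CLASSES = frozenset(
    {"edited_variant", "unedited_variant", "marker", "adar", "other"}
)
VARIANT_CLASSES = frozenset({"edited_variant", "unedited_variant"})

CSV_COLUMNS = [
    "target_name",
    "barcode",
    "probe_class",
    "site_id",
    "cell_class",
    "transcript_group",
]


class CodebookError(ValueError):
    """Raised when a codebook violates its structural invariants."""


@dataclass(frozen=True)
class CodebookEntry:
    """One probe: a barcode and what it reports."""

    target_name: str
    barcode: str
    probe_class: str
    site_id: str | None = None
    cell_class: str | None = None
    transcript_group: str | None = None


class Codebook:
    """Validated collection of :class:`CodebookEntry`, indexed by barcode and site.

    Parameters
    ----------
    entries:
        Iterable of :class:`CodebookEntry`.  Validation enforces: constant
        barcode length over the {A,C,G,T} alphabet, barcode uniqueness,
        exactly one edited and one unedited probe per ``site_id``, and
        ``site_id`` present on every variant probe.
    """

    def __init__(self, entries):
        self.entries: list[CodebookEntry] = list(entries)
        self._validate()
        self._by_barcode = {e.barcode: e for e in self.entries}
        self._by_site: dict[str, dict[str, CodebookEntry]] = {}
        for e in self.entries:
            if e.probe_class in VARIANT_CLASSES:
                self._by_site.setdefault(e.site_id, {})[e.probe_class] = e

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if not self.entries:
            return
        length = len(self.entries[0].barcode)
        seen: set[str] = set()
        site_classes: dict[str, list[str]] = {}
        for e in self.entries:
            if e.probe_class not in PROBE_CLASSES:
                raise CodebookError(
                    f"unknown probe_class {e.probe_class!r} for {e.target_name}"
                )
            if len(e.barcode) != length:
                raise CodebookError(
                    f"barcode {e.barcode!r} has length {len(e.barcode)}, "
                    f"expected {length}"
                )
            if any(b not in ALPHABET for b in e.barcode):
                raise CodebookError(f"barcode {e.barcode!r} has non-ACGT character")
            if e.barcode in seen:
                raise CodebookError(f"duplicate barcode {e.barcode}")
            seen.add(e.barcode)
            if e.probe_class in VARIANT_CLASSES:
                if not e.site_id:
                    raise CodebookError(
                        f"variant probe {e.target_name} is missing site_id"
                    )
                site_classes.setdefault(e.site_id, []).append(e.probe_class)
        for site, classes in site_classes.items():
            if sorted(classes) != ["edited_variant", "unedited_variant"]:
                raise CodebookError(
                    f"site {site} must have exactly one edited_variant and one "
                    f"unedited_variant, got {sorted(classes)}"
                )

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Codebook):
            return NotImplemented
        return sorted(self.entries, key=lambda e: e.barcode) == sorted(
            other.entries, key=lambda e: e.barcode
        )

    @property
    def n_cycles(self) -> int:
        """Barcode length L = number of sequencing cycles."""
        if not self.entries:
            raise CodebookError("empty codebook has no cycle count")
        return len(self.entries[0].barcode)

    def lookup(self, barcode: str) -> str:
        """Target name for ``barcode``, or :data:`UNMATCHED` if absent."""
        e = self._by_barcode.get(barcode)
        return e.target_name if e is not None else UNMATCHED

    def entry_for_barcode(self, barcode: str) -> CodebookEntry | None:
        return self._by_barcode.get(barcode)

    def entry_for_target(self, target_name: str) -> CodebookEntry:
        for e in self.entries:
            if e.target_name == target_name:
                return e
        raise KeyError(target_name)

    @property
    def barcodes(self) -> list[str]:
        return [e.barcode for e in self.entries]

    def site_pairs(self) -> list[tuple[str, str, str]]:
        """``(site_id, edited_barcode, unedited_barcode)``, sorted by site_id."""
        out = []
        for site in sorted(self._by_site):
            pair = self._by_site[site]
            out.append(
                (site, pair["edited_variant"].barcode, pair["unedited_variant"].barcode)
            )
        return out

    @property
    def site_ids(self) -> list[str]:
        return sorted(self._by_site)

    def variant_entries(self, site_id: str) -> tuple[CodebookEntry, CodebookEntry]:
        """(edited, unedited) entries for one site."""
        pair = self._by_site[site_id]
        return pair["edited_variant"], pair["unedited_variant"]

    def markers(self) -> list[CodebookEntry]:
        return [e for e in self.entries if e.probe_class == "marker"]

    def marker_class_of(self, target_name: str) -> str | None:
        e = self.entry_for_target(target_name)
        return e.cell_class if e.probe_class == "marker" else None

    def adar_entries(self) -> list[CodebookEntry]:
        return [e for e in self.entries if e.probe_class == "adar"]

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(e) for e in self.entries], columns=CSV_COLUMNS)
        return df

    def save(self, path, format: str | None = None) -> None:
        path = Path(path)
        fmt = format or _infer_format(path)
        if fmt == "csv":
            self.to_frame().to_csv(path, index=False)
        elif fmt == "json":
            records = [
                {k: v for k, v in asdict(e).items()} for e in self.entries
            ]
            path.write_text(json.dumps(records, indent=1))
        else:
            raise ValueError(f"unknown codebook format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    return "json" if suffix == "json" else "csv"


def _entry_from_record(rec: dict) -> CodebookEntry:
    def _clean(v):
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return str(v)

    return CodebookEntry(
        target_name=str(rec["target_name"]),
        barcode=str(rec["barcode"]),
        probe_class=str(rec["probe_class"]),
        site_id=_clean(rec.get("site_id")),
        cell_class=_clean(rec.get("cell_class")),
        transcript_group=_clean(rec.get("transcript_group")),
    )


def load_codebook(path, format: str | None = None) -> Codebook:
    """Load and validate a codebook from CSV or JSON.

    CSV must carry the header ``target_name,barcode,probe_class,site_id,
    cell_class,transcript_group``; JSON is a list of objects with the same
    keys.  Raises :class:`CodebookError` on any structural violation
    (duplicate barcode, unpaired site, bad alphabet or length).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str)
        missing = {"target_name", "barcode", "probe_class"} - set(df.columns)
        if missing:
            raise CodebookError(f"codebook CSV missing columns: {sorted(missing)}")
        records = df.to_dict("records")
    elif fmt == "json":
        records = json.loads(path.read_text())
    else:
        raise ValueError(f"unknown codebook format {fmt!r}")
    return Codebook(_entry_from_record(r) for r in records)
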