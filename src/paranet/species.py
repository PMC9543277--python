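"""Species-name normalisation shared by the range and interaction readers.

Range maps and interaction lists rarely agree on taxonomy out of the box.
The join key used throughout this package is a normalised name: lowercased,
whitespace-collapsed, with optional user-supplied synonym mapping applied
after normalisation.  The synonym table is the user's concern (taxonomic
checklists differ); the package only provides the mechanism.
"""

from __future__ import annotations

import csv


def normalize_species_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Lowercase, trim and collapse internal whitespace; then map synonyms."""
    key = " ".join(str(name).strip().lower().split())
    if not key:
        raise ValueError("empty species name")
    if synonyms:
        key = synonyms.get(key, key)
    return key


def read_synonyms(path) -> dict[str, str]:
    """Read a two-column CSV (synonym, accepted_name) into a lookup table.

    Both columns are normalised, so the table itself may use any casing.
    """
    table: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"synonym row needs 2 columns, got: {row}")
            table[normalize_species_name(row[0])] = normalize_species_name(row[1])
    return table
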