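"""Local terminology mapping: EHR/CPOE codes onto canonical concepts.

The hospital side does not use standardised terminology, so every local
concept (drug, route, unit, frequency, lab test, allergen) is mapped by
hand onto its canonical counterpart.  Resolution is a pure lookup: an
unmapped code yields a typed :class:`Unmapped` outcome and the calling
rule is skipped for that item with an explicit note — local codes never
leak into dose arithmetic.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Union

import pandas as pd

from .model import ConceptRef, LocalConceptMapping, MAPPING_DOMAINS


class MappingLoadError(ValueError):
    """Duplicate local codes or dangling canonical targets."""


@dataclass(frozen=True)
class Unmapped:
    """Typed outcome for a local code with no canonical mapping."""

    local_code: str
    domain: str

    @property
    def reason(self) -> str:
        return f"unmapped {self.domain} concept {self.local_code!r}"


class MappingSet:
    """The loaded local→canonical map; resolution is pure and total."""

    def __init__(self, mappings: list[LocalConceptMapping], version: str = ""):
        self._by_key: dict[tuple[str, str], LocalConceptMapping] = {}
        for m in mappings:
            key = (m.local_code, m.domain)
            if key in self._by_key:
                raise MappingLoadError(f"duplicate mapping for {key}")
            self._by_key[key] = m
        self.version = version

    def __len__(self) -> int:
        return len(self._by_key)

    @property
    def mappings(self) -> list[LocalConceptMapping]:
        return list(self._by_key.values())

    def resolve(self, local_code: str, domain: str) -> Union[ConceptRef, Unmapped]:
        if domain not in MAPPING_DOMAINS:
            raise ValueError(f"unknown mapping domain: {domain!r}")
        m = self._by_key.get((local_code, domain))
        if m is None:
            return Unmapped(local_code=local_code, domain=domain)
        return m.target


def load_mappings(
    table: Union[str, Path, pd.DataFrame],
    iri_exists: Optional[Callable[[str], bool]] = None,
    label_for: Optional[Callable[[str], str]] = None,
) -> MappingSet:
    """Load the mapping CSV (local_code, local_label, domain, target_iri).

    Every target is validated against the knowledge base via
    ``iri_exists``; duplicates and dangling targets are load errors.
    The mapping set is versioned by the content hash of its table.
    """
    if isinstance(table, pd.DataFrame):
        df = table
        raw = df.to_csv(index=False).encode()
    else:
        raw = Path(table).read_bytes()
        df = pd.read_csv(io.BytesIO(raw), dtype=str).fillna("")
    required = {"local_code", "local_label", "domain", "target_iri"}
    missing = required - set(df.columns)
    if missing:
        raise MappingLoadError(f"mapping table missing columns: {sorted(missing)}")
    mappings = []
    errors = []
    for row in df.itertuples(index=False):
        target_iri = str(row.target_iri)
        if iri_exists is not None and not iri_exists(target_iri):
            errors.append(
                f"mapping {row.local_code}/{row.domain} targets "
                f"missing concept {target_iri}"
            )
            continue
        label = str(row.local_label) or str(row.local_code)
        target_label = label_for(target_iri) if label_for else label
        mappings.append(
            LocalConceptMapping(
                local_code=str(row.local_code),
                local_label=label,
                domain=str(row.domain),
                target=ConceptRef(iri=target_iri, label=target_label or target_iri),
            )
        )
    if errors:
        raise MappingLoadError("; ".join(errors))
    version = hashlib.sha256(raw).hexdigest()[:16]
    return MappingSet(mappings, version=version)


def mappings_to_frame(ms: MappingSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "local_code": m.local_code,
                "local_label": m.local_label,
                "domain": m.domain,
                "target_iri": m.target.iri,
            }
            for m in ms.mappings
        ],
        columns=["local_code", "local_label", "domain", "target_iri"],
    )
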