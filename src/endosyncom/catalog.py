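"""Strain catalog for a culturable endophyte panel.

The default panel mirrors a screen of endophytes cultured from the medicinal
liana *Schisandra sphenanthera*: 27 bacterial isolates across four phyla
(Firmicutes, Bacteroidetes, Actinobacteria, Proteobacteria) and 26 fungal
isolates across three (Ascomycota, Basidiomycota, Zygomycota), each carried as
a genus-level identification plus an isolate code.

Arbitrary panels can be generated for simulation studies with
:func:`generate_catalog`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

BACTERIUM = "bacterium"
FUNGUS = "fungus"

BACTERIAL_PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria")
FUNGAL_PHYLA = ("Ascomycota", "Basidiomycota", "Zygomycota")

#: phylum -> kingdom lookup used when a profile mixes both kingdoms
PHYLUM_KINGDOM: dict[str, str] = {
    **{p: BACTERIUM for p in BACTERIAL_PHYLA},
    **{p: FUNGUS for p in FUNGAL_PHYLA},
}

# (phylum, genus, isolate code) for the default 27-bacterium panel.
# One isolate code was printed twice in the source records (SLB15); the
# Rhizobium isolate is carried here under the unused code SLB16 so that
# codes stay unique.
_DEFAULT_BACTERIA: tuple[tuple[str, str, str], ...] = (
    ("Firmicutes", "Bacillus", "SLB12"),
    ("Firmicutes", "Lysinibacillus", "SRB6"),
    ("Firmicutes", "Viridibacilus", "SFB11"),
    ("Firmicutes", "Romboutsia", "SRB23"),
    ("Firmicutes", "Straphylococcus", "SSB39"),
    ("Firmicutes", "Enterococcus", "SLB1"),
    ("Firmicutes", "Brevibacillus", "SFB12"),
    ("Bacteroidetes", "Flavobacterium", "SSB1"),
    ("Bacteroidetes", "Sphingobacterium", "SRB12"),
    ("Bacteroidetes", "Mucilaginibacter", "SSB4"),
    ("Bacteroidetes", "Wautersiella", "SSB19"),
    ("Bacteroidetes", "Alloprevotella", "SLB9"),
    ("Actinobacteria", "Nocardioides", "SSB16"),
    ("Actinobacteria", "Micrococcus", "SLB31"),
    ("Actinobacteria", "Brevibacterium", "SLB15"),
    ("Actinobacteria", "Kocuria", "SLB14"),
    ("Proteobacteria", "Pantoea", "SSB8"),
    ("Proteobacteria", "Burkholderia", "SRB18"),
    ("Proteobacteria", "Serratia", "SFB13"),
    ("Proteobacteria", "Xanthomonas", "SFB7"),
    ("Proteobacteria", "Limnobacter", "SLB7"),
    ("Proteobacteria", "Duganella", "SRB22"),
    ("Proteobacteria", "Rhizobium", "SLB16"),
    ("Proteobacteria", "Agrobacterium", "SSB31"),
    ("Proteobacteria", "Herbaspirillum", "SFB6"),
    ("Proteobacteria", "Stenotrophomonas", "SSB25"),
    ("Proteobacteria", "Enterobacter", "SLB11"),
)

_DEFAULT_FUNGI: tuple[tuple[str, str, str], ...] = (
    ("Ascomycota", "Pestalotiopsis", "SRF21"),
    ("Ascomycota", "Trichoderma", "SSF13"),
    ("Ascomycota", "Colletotrichum", "SSF14"),
    ("Ascomycota", "Fusarium", "SFF11"),
    ("Ascomycota", "Lasiodiplodia", "SLF1"),
    ("Ascomycota", "Bipolaris", "SSF12"),
    ("Ascomycota", "Penicillium", "SRF9"),
    ("Ascomycota", "Diaporthe", "SLF18"),
    ("Ascomycota", "Daldinia", "SLF4"),
    ("Ascomycota", "Neopestalotiopsis", "SLF5"),
    ("Ascomycota", "Beltrania", "SLF21"),
    ("Ascomycota", "Guignardia", "SLF6"),
    ("Ascomycota", "Phomopsis", "SFF9"),
    ("Ascomycota", "Botryosphaeria", "SRF16"),
    ("Ascomycota", "Hypoxylon", "SLF24"),
    ("Ascomycota", "Eutypella", "SSF11"),
    ("Ascomycota", "Hyphopichia", "SFF7"),
    ("Basidiomycota", "Clitopilus", "SSF19"),
    ("Basidiomycota", "Ceratobasidium", "SFF6"),
    ("Basidiomycota", "Phlebiopsis", "SSF18"),
    ("Basidiomycota", "Emmia", "SFF12"),
    ("Basidiomycota", "Irpex", "SRF17"),
    ("Basidiomycota", "Phlebia", "SLF27"),
    ("Basidiomycota", "Perenniporia", "SLF26"),
    ("Zygomycota", "Umbelopsis", "SLF28"),
    ("Zygomycota", "Mucor", "SRF1"),
)


@dataclass(frozen=True)
class StrainRecord:
    """One catalogued isolate."""

    code: str
    kingdom: str
    phylum: str
    genus: str

    def __post_init__(self) -> None:
        if self.kingdom not in (BACTERIUM, FUNGUS):
            raise ValueError(f"unknown kingdom {self.kingdom!r}")


class StrainCatalog:
    """An ordered collection of :class:`StrainRecord` with unique codes."""

    def __init__(self, strains: Iterable[StrainRecord]):
        self.strains: tuple[StrainRecord, ...] = tuple(strains)
        codes = [s.code for s in self.strains]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate strain codes: {dupes}")
        self._by_code = {s.code: s for s in self.strains}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.strains)

    def __iter__(self) -> Iterator[StrainRecord]:
        return iter(self.strains)

    def __contains__(self, code: object) -> bool:
        return code in self._by_code

    def __eq__(self, other: object) -> bool:
        return isinstance(other, StrainCatalog) and self.strains == other.strains

    def get(self, code: str) -> StrainRecord:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"strain code {code!r} not in catalog") from None

    # -- views --------------------------------------------------------------
    @property
    def bacteria(self) -> tuple[StrainRecord, ...]:
        return tuple(s for s in self.strains if s.kingdom == BACTERIUM)

    @property
    def fungi(self) -> tuple[StrainRecord, ...]:
        return tuple(s for s in self.strains if s.kingdom == FUNGUS)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(s.code for s in self.strains)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [s.code for s in self.strains],
                "kingdom": [s.kingdom for s in self.strains],
                "phylum": [s.phylum for s in self.strains],
                "genus": [s.genus for s in self.strains],
            }
        )

    def phylum_counts(self, kingdom: str | None = None) -> pd.Series:
        """Number of strains per phylum, optionally restricted to one kingdom."""
        strains = self.strains if kingdom is None else tuple(
            s for s in self.strains if s.kingdom == kingdom
        )
        counts: dict[str, int] = {}
        for s in strains:
            counts[s.phylum] = counts.get(s.phylum, 0) + 1
        return pd.Series(counts, dtype=int, name="n_strains")


def default_catalog() -> StrainCatalog:
    """The default 27-bacterium / 26-fungus screening panel."""
    records = [
        StrainRecord(code, BACTERIUM, phylum, genus)
        for phylum, genus, code in _DEFAULT_BACTERIA
    ] + [
        StrainRecord(code, FUNGUS, phylum, genus)
        for phylum, genus, code in _DEFAULT_FUNGI
    ]
    return StrainCatalog(records)


def _proportional_allocation(n: int, weights: Sequence[int]) -> list[int]:
    """Largest-remainder split of ``n`` items proportional to ``weights``."""
    total = sum(weights)
    if total == 0:
        return [0] * len(weights)
    raw = [n * w / total for w in weights]
    alloc = [int(np.floor(x)) for x in raw]
    remainder = n - sum(alloc)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for i in range(remainder):
        alloc[order[i]] += 1
    return alloc


def generate_catalog(
    n_bacteria: int = 27,
    n_fungi: int = 26,
    phylum_profile: Mapping[str, int] | None = None,
    seed: int = 42,
) -> StrainCatalog:
    """Build a strain catalog for simulation.

    Parameters
    ----------
    n_bacteria, n_fungi
        Panel sizes per kingdom (non-negative).
    phylum_profile
        Optional phylum -> strain count map covering both kingdoms.  Counts
        must sum to ``n_bacteria`` within bacterial phyla and ``n_fungi``
        within fungal phyla.  When omitted, the default panel's phylum
        proportions are used; with the default sizes (27, 26) the default
        panel itself is returned.
    seed
        Seed for genus sampling; identical inputs give identical catalogs.
    """
    if n_bacteria < 0 or n_fungi < 0:
        raise ValueError("panel sizes must be non-negative")

    if phylum_profile is None and n_bacteria == 27 and n_fungi == 26:
        return default_catalog()

    if phylum_profile is None:
        b_alloc = _proportional_allocation(
            n_bacteria, [sum(1 for p, _, _ in _DEFAULT_BACTERIA if p == ph) for ph in BACTERIAL_PHYLA]
        )
        f_alloc = _proportional_allocation(
            n_fungi, [sum(1 for p, _, _ in _DEFAULT_FUNGI if p == ph) for ph in FUNGAL_PHYLA]
        )
        profile = {**dict(zip(BACTERIAL_PHYLA, b_alloc)), **dict(zip(FUNGAL_PHYLA, f_alloc))}
    else:
        profile = dict(phylum_profile)
        unknown = sorted(set(profile) - set(PHYLUM_KINGDOM))
        if unknown:
            raise ValueError(f"unknown phyla in profile: {unknown}")

    b_sum = sum(c for p, c in profile.items() if PHYLUM_KINGDOM[p] == BACTERIUM)
    f_sum = sum(c for p, c in profile.items() if PHYLUM_KINGDOM[p] == FUNGUS)
    if b_sum != n_bacteria or f_sum != n_fungi:
        raise ValueError(
            f"phylum profile sums ({b_sum} bacteria, {f_sum} fungi) do not match "
            f"requested panel sizes ({n_bacteria}, {n_fungi})"
        )
    if any(c < 0 for c in profile.values()):
        raise ValueError("phylum counts must be non-negative")

    rng = np.random.default_rng(seed)
    genus_pool: dict[str, list[str]] = {}
    for ph in BACTERIAL_PHYLA:
        genus_pool[ph] = [g for p, g, _ in _DEFAULT_BACTERIA if p == ph]
    for ph in FUNGAL_PHYLA:
        genus_pool[ph] = [g for p, g, _ in _DEFAULT_FUNGI if p == ph]

    records: list[StrainRecord] = []
    counters = {BACTERIUM: 0, FUNGUS: 0}
    prefix = {BACTERIUM: "B", FUNGUS: "F"}
    for ph in list(BACTERIAL_PHYLA) + list(FUNGAL_PHYLA):
        count = profile.get(ph, 0)
        kingdom = PHYLUM_KINGDOM[ph]
        pool = genus_pool.get(ph) or [f"{ph}-genus"]
        for _ in range(count):
            counters[kingdom] += 1
            genus = pool[int(rng.integers(len(pool)))]
            code = f"{prefix[kingdom]}{counters[kingdom]:03d}"
            records.append(StrainRecord(code, kingdom, ph, genus))
    return StrainCatalog(records)
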