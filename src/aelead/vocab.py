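"""Coded AE vocabulary and free-text lexicon.

Regulatory reports carry coded preferred terms (PTs) organised in a
four-level hierarchy (SOC > HLGT > HLT > PT), mirroring the structure of
regulatory AE dictionaries. Social-media reviews carry free text, which is
mapped to reviewer-style AE category labels by a deterministic,
case-insensitive phrase lexicon. A small synthetic vocabulary covering the
most frequent AE concepts for a statin-like and an anorectic-like drug
ships with the package; real regulatory dictionaries are licensed and are
deliberately not bundled.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

_DATA = resources.files("aelead.data")


@dataclass(frozen=True)
class SpecificAE:
    """A named clinically-important AE filter.

    Membership is defined on both streams: by reviewer category labels on
    the social-media side and by PT / HLT / SOC sets on the regulatory
    side.
    """

    name: str
    categories: frozenset[str] = field(default_factory=frozenset)
    pts: frozenset[str] = field(default_factory=frozenset)
    hlts: frozenset[str] = field(default_factory=frozenset)
    socs: frozenset[str] = field(default_factory=frozenset)

    def matches_categories(self, categories: Iterable[str]) -> bool:
        return not self.categories.isdisjoint(categories)


class TermHierarchy:
    """Four-level coded AE vocabulary plus a free-text category lexicon.

    Parameters
    ----------
    chains
        Mapping ``pt -> (hlt, hlgt, soc)``. Every PT maps to exactly one
        chain; duplicate PTs raise ``ValueError``.
    lexicon
        Mapping ``category label -> list of lowercase trigger phrases``.
    specific
        Named :class:`SpecificAE` filters, keyed by name.
    hearsay_triggers, serious_triggers
        Lowercase phrases marking second-hand reports and FDA-style
        serious outcomes (death, hospitalization, disability, permanent
        damage, intervention to prevent permanent impairment).
    category_map
        Optional cross-stream concept map ``sm category -> regulatory
        category`` used for overlap counting.
    """

    def __init__(
        self,
        chains: Mapping[str, tuple[str, str, str]],
        lexicon: Mapping[str, Iterable[str]],
        specific: Mapping[str, SpecificAE] | None = None,
        hearsay_triggers: Iterable[str] = (),
        serious_triggers: Iterable[str] = (),
        category_map: Mapping[str, str] | None = None,
    ):
        self.chains = dict(chains)
        self.lexicon = {c: tuple(p) for c, p in lexicon.items()}
        for cat, phrases in self.lexicon.items():
            if not phrases or any(not p for p in phrases):
                raise ValueError(f"lexicon category {cat!r} has an empty phrase")
        self.specific = dict(specific or {})
        self.hearsay_triggers = tuple(t.lower() for t in hearsay_triggers)
        self.serious_triggers = tuple(t.lower() for t in serious_triggers)
        self.category_map = dict(category_map or {})
        self._hlt_to_pts: dict[str, list[str]] = {}
        for pt, (hlt, _hlgt, _soc) in self.chains.items():
            self._hlt_to_pts.setdefault(hlt, []).append(pt)

    # -- coded side -------------------------------------------------------
    def hlt(self, pt: str) -> str:
        return self.chains[pt][0]

    def hlgt(self, pt: str) -> str:
        return self.chains[pt][1]

    def soc(self, pt: str) -> str:
        return self.chains[pt][2]

    def pts_in_hlt(self, hlt: str) -> list[str]:
        return sorted(self._hlt_to_pts.get(hlt, []))

    @property
    def hlts(self) -> list[str]:
        return sorted(self._hlt_to_pts)

    def categories_of_pts(self, pts: Iterable[str], level: str = "hlt") -> set[str]:
        """Map coded PTs to category labels at ``hlt`` or ``hlgt`` level.

        Unknown PTs are logged and skipped, never fatal.
        """
        if level not in ("hlt", "hlgt"):
            raise ValueError("level must be 'hlt' or 'hlgt'")
        out: set[str] = set()
        for pt in pts:
            chain = self.chains.get(pt)
            if chain is None:
                logger.warning("unknown preferred term %r skipped", pt)
                continue
            out.add(chain[0] if level == "hlt" else chain[1])
        return out

    def specific_flag_for_pts(self, name: str, pts: Iterable[str]) -> bool:
        d = self.specific[name]
        for pt in pts:
            chain = self.chains.get(pt)
            if pt in d.pts:
                return True
            if chain is not None and (chain[0] in d.hlts or chain[2] in d.socs):
                return True
        return False

    # -- free-text side ---------------------------------------------------
    def categories_of_text(self, text: str) -> set[str]:
        low = text.lower()
        return {c for c, phrases in self.lexicon.items() if any(p in low for p in phrases)}

    def is_hearsay(self, text: str) -> bool:
        low = text.lower()
        return any(t in low for t in self.hearsay_triggers)

    def is_serious_text(self, text: str) -> bool:
        low = text.lower()
        return any(t in low for t in self.serious_triggers)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_files(
        cls,
        hierarchy_csv,
        lexicon_csv,
        specific_csv=None,
        triggers_csv=None,
        category_map_csv=None,
        drug: str | None = None,
    ) -> "TermHierarchy":
        """Build a vocabulary from plain CSV data files.

        ``drug`` filters the drug-scoped lexicon / specific-AE tables; the
        hierarchy and triggers are shared across drugs.
        """
        h = pd.read_csv(hierarchy_csv)
        for col in ("pt", "hlt", "hlgt", "soc"):
            if col not in h.columns:
                raise ValueError(f"hierarchy file missing column {col!r}")
        if h["pt"].duplicated().any():
            dups = h.loc[h["pt"].duplicated(), "pt"].tolist()
            raise ValueError(f"preferred terms with multiple chains: {dups}")
        chains = {r.pt: (r.hlt, r.hlgt, r.soc) for r in h.itertuples()}

        lex = pd.read_csv(lexicon_csv)
        if "drug" in lex.columns and drug is not None:
            lex = lex[lex["drug"] == drug]
        lexicon: dict[str, list[str]] = {}
        for r in lex.itertuples():
            lexicon.setdefault(r.category, []).append(str(r.phrase).lower())

        specific: dict[str, SpecificAE] = {}
        if specific_csv is not None:
            sp = pd.read_csv(specific_csv)
            if "drug" in sp.columns and drug is not None:
                sp = sp[sp["drug"] == drug]
            for name, grp in sp.groupby("name"):
                parts = {k: frozenset(grp.loc[grp["kind"] == k, "value"]) for k in ("category", "pt", "hlt", "soc")}
                specific[name] = SpecificAE(
                    name=name,
                    categories=parts["category"],
                    pts=parts["pt"],
                    hlts=parts["hlt"],
                    socs=parts["soc"],
                )

        hearsay: list[str] = []
        serious: list[str] = []
        if triggers_csv is not None:
            tr = pd.read_csv(triggers_csv)
            hearsay = tr.loc[tr["kind"] == "hearsay", "phrase"].tolist()
            serious = tr.loc[tr["kind"] == "serious", "phrase"].tolist()

        cmap: dict[str, str] = {}
        if category_map_csv is not None:
            cm = pd.read_csv(category_map_csv)
            cmap = dict(zip(cm["sm_category"], cm["reg_category"]))

        return cls(chains, lexicon, specific, hearsay, serious, cmap)


def default_vocabulary(drug: str) -> TermHierarchy:
    """The bundled synthetic vocabulary, scoped to one drug's lexicon."""
    if drug not in ("atorvastatin", "sibutramine"):
        raise ValueError(f"no bundled vocabulary for drug {drug!r}")
    return TermHierarchy.from_files(
        _DATA / "hierarchy.csv",
        _DATA / "lexicon.csv",
        _DATA / "specific_aes.csv",
        _DATA / "triggers.csv",
        _DATA / "category_map.csv",
        drug=drug,
    )
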