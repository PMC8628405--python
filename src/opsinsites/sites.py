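"""Reference-numbered functional-site mapping and classification.

Functional sites are defined in the numbering of a reference protein —
bovine rhodopsin for opsins, human RLBP1 (CRALBP) for CRAL_TRIO proteins —
and carried onto query sequences through a global pairwise alignment.  On top
of the per-site calls sit three classifiers:

* counterion / bistability: a negatively charged residue (E or D) mapped to
  the rhodopsin counterion position 113 predicts a monostable-like pigment;
  an uncharged residue there is the bistable-like signature shared by
  photoisomerase-family opsins such as retinochrome and RGR.
* G-protein-coupling competence: the four interacting residue pairs
  D83/N302, R135/Y223, K231/E247, Y306/F313 and the NPXXY motif (302-306).
* the 10-site RLBP1 retinoid-binding score: W166, Y180, F198, C199, M209,
  Q211, M223, V224, M226, W245.

"Conserved" means identity with the site's expected residue set, which
defaults to the single reference residue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import GAP, PairwiseAlignment, SubstitutionMatrix, nw_align
from .errors import SchemeError

ROLE_COUNTERION = "counterion"
ROLE_GPROTEIN = "gprotein"
ROLE_RLBP1 = "rlbp1_critical"
_ROLES = {ROLE_COUNTERION, ROLE_GPROTEIN, ROLE_RLBP1}

#: Residues accepted as "charged" at the counterion position (E plus the
#: only other negatively charged amino acid, D).
CHARGED_COUNTERION = {"E", "D"}

STATUS_MATCH = "match"
STATUS_MISMATCH = "mismatch"
STATUS_UNALIGNED = "unaligned"

STATE_CHARGED = "charged"
STATE_UNCHARGED = "uncharged"
INDETERMINATE = "indeterminate"
MONOSTABLE = "monostable-like"
BISTABLE = "bistable-like"

PAIR_INTACT = "intact"
PAIR_BROKEN = "broken"


@dataclass(frozen=True)
class SiteSpec:
    label: str
    ref_position: int  # 1-based index into the reference sequence
    expected_residues: frozenset[str]
    role: str

    def __post_init__(self):
        if self.role not in _ROLES:
            raise SchemeError(f"site {self.label!r}: unknown role {self.role!r}")
        if not self.expected_residues:
            raise SchemeError(f"site {self.label!r}: empty expected residue set")
        if self.ref_position < 1:
            raise SchemeError(f"site {self.label!r}: positions are 1-based")


@dataclass(frozen=True)
class PairRule:
    label: str
    member_labels: tuple[str, str]


@dataclass(frozen=True)
class MotifRule:
    """An anchored motif in reference numbering, e.g. NPXXY at 302-306."""

    label: str
    anchors: dict[int, str]  # ref_position -> expected residue
    wildcards: frozenset[int]

    def positions(self) -> list[int]:
        return sorted(set(self.anchors) | self.wildcards)


@dataclass(frozen=True)
class ReferenceScheme:
    scheme_id: str
    reference_seq: str
    sites: tuple[SiteSpec, ...]
    pairs: tuple[PairRule, ...] = ()
    motifs: tuple[MotifRule, ...] = ()

    def __post_init__(self):
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise SchemeError("duplicate site labels")
        by_pos = {}
        for s in self.sites:
            if s.ref_position > len(self.reference_seq):
                raise SchemeError(
                    f"site {s.label!r}: position {s.ref_position} beyond "
                    f"reference length {len(self.reference_seq)}"
                )
            ref_res = self.reference_seq[s.ref_position - 1]
            if ref_res not in s.expected_residues:
                raise SchemeError(
                    f"site {s.label!r}: reference carries {ref_res!r} at "
                    f"{s.ref_position}, not in expected set "
                    f"{sorted(s.expected_residues)}"
                )
            by_pos[s.ref_position] = s
        known = set(labels)
        for p in self.pairs:
            for m in p.member_labels:
                if m not in known:
                    raise SchemeError(f"pair {p.label!r}: unknown member {m!r}")
        for mo in self.motifs:
            pos = mo.positions()
            if pos != list(range(pos[0], pos[-1] + 1)):
                raise SchemeError(f"motif {mo.label!r}: positions not contiguous")
            for ap, res in mo.anchors.items():
                if ap not in by_pos:
                    raise SchemeError(
                        f"motif {mo.label!r}: no site defined at anchor {ap}"
                    )
                if res not in by_pos[ap].expected_residues:
                    raise SchemeError(
                        f"motif {mo.label!r}: anchor {ap} expects {res!r} but "
                        f"the site there expects {sorted(by_pos[ap].expected_residues)}"
                    )

    def sites_by_role(self, role: str) -> list[SiteSpec]:
        return [s for s in self.sites if s.role == role]

    def site(self, label: str) -> SiteSpec:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass(frozen=True)
class SiteCall:
    site_label: str
    query_position: int | None
    observed: str | None
    status: str

    def __post_init__(self):
        if (self.status == STATUS_UNALIGNED) != (self.query_position is None):
            raise SchemeError("unaligned iff query_position is None")


@dataclass
class FunctionalProfile:
    """Per-sequence classification summary.

    Fields that a scheme does not define (e.g. rlbp1_score under the opsin
    scheme) are ``None``; reports render them as '.'.
    """

    seq_id: str
    scheme_id: str
    site_calls: list[SiteCall]
    counterion_state: str | None = None
    stability_prediction: str | None = None
    pair_status: dict[str, str] = field(default_factory=dict)
    motif_status: str | None = None
    signaling_intact_count: int | None = None
    deviations: list[str] = field(default_factory=list)
    rlbp1_score: int | None = None


# ---------------------------------------------------------------------------
# Scheme config format


def parse_scheme(text: str, scheme_id_hint: str | None = None) -> ReferenceScheme:
    """Parse the plain-text scheme config.

    Key-value lines (``key = value``); repeated ``site``/``pair``/``motif``
    keys accumulate.  Sites are ``label=position:expected_residues:role``,
    pairs ``label=member1,member2`` and motifs
    ``label=pos:res,pos:res,...`` (unlisted positions inside the motif span
    are wildcards).  ``#`` starts a comment.
    """
    scheme_id = scheme_id_hint
    reference = None
    sites: list[SiteSpec] = []
    pairs: list[PairRule] = []
    motifs: list[MotifRule] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemeError(f"line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key == "scheme_id":
            scheme_id = value
        elif key == "reference":
            reference = value
        elif key == "site":
            try:
                label, spec = value.split("=", 1)
                pos_s, residues, role = spec.split(":")
                sites.append(
                    SiteSpec(
                        label=label.strip(),
                        ref_position=int(pos_s),
                        expected_residues=frozenset(residues.strip()),
                        role=role.strip(),
                    )
                )
            except ValueError as exc:
                raise SchemeError(f"line {lineno}: bad site spec: {value!r}") from exc
        elif key == "pair":
            try:
                label, members = value.split("=", 1)
                m1, m2 = (m.strip() for m in members.split(","))
            except ValueError as exc:
                raise SchemeError(f"line {lineno}: bad pair spec: {value!r}") from exc
            pairs.append(PairRule(label=label.strip(), member_labels=(m1, m2)))
        elif key == "motif":
            try:
                label, anchors_s = value.split("=", 1)
                anchors = {}
                for item in anchors_s.split(","):
                    pos_s, res = item.split(":")
                    anchors[int(pos_s)] = res.strip()
            except ValueError as exc:
                raise SchemeError(f"line {lineno}: bad motif spec: {value!r}") from exc
            span = range(min(anchors), max(anchors) + 1)
            motifs.append(
                MotifRule(
                    label=label.strip(),
                    anchors=anchors,
                    wildcards=frozenset(p for p in span if p not in anchors),
                )
            )
        else:
            raise SchemeError(f"line {lineno}: unknown key {key!r}")
    if scheme_id is None:
        raise SchemeError("scheme_id missing")
    if reference is None:
        raise SchemeError("reference sequence missing")
    return ReferenceScheme(
        scheme_id=scheme_id,
        reference_seq=reference,
        sites=tuple(sites),
        pairs=tuple(pairs),
        motifs=tuple(motifs),
    )


_PACKAGED = {
    "bovine_rhodopsin": "bovine_rhodopsin.txt",
    "human_RLBP1": "human_RLBP1_synthetic.txt",
}


def load_scheme(name_or_path: str | Path) -> ReferenceScheme:
    """Load a packaged scheme by id or a user scheme config by path."""
    name = str(name_or_path)
    if name in _PACKAGED:
        text = (
            resources.files("opsinsites.schemes")
            .joinpath(_PACKAGED[name])
            .read_text()
        )
        return parse_scheme(text)
    path = Path(name_or_path)
    if not path.exists():
        raise SchemeError(
            f"unknown scheme {name!r}: not packaged "
            f"({sorted(_PACKAGED)}) and no such file"
        )
    return parse_scheme(path.read_text())


# ---------------------------------------------------------------------------
# Operations


def map_sites(aln: PairwiseAlignment, scheme: ReferenceScheme) -> list[SiteCall]:
    """One SiteCall per scheme site, walking the alignment columns.

    A gap in the query opposite the reference position yields an unaligned
    call; ``X`` in the query never counts as a match.
    """
    if aln.ref != scheme.reference_seq:
        raise SchemeError(
            f"alignment reference does not match scheme {scheme.scheme_id!r}"
        )
    wanted = {s.ref_position: s for s in scheme.sites}
    calls: dict[int, SiteCall] = {}
    ref_pos = 0
    query_pos = 0
    for qc, rc in zip(aln.aligned_query, aln.aligned_ref):
        if qc != GAP:
            query_pos += 1
        if rc != GAP:
            ref_pos += 1
            site = wanted.get(ref_pos)
            if site is not None:
                if qc == GAP:
                    calls[ref_pos] = SiteCall(site.label, None, None, STATUS_UNALIGNED)
                else:
                    status = (
                        STATUS_MATCH
                        if qc in site.expected_residues
                        else STATUS_MISMATCH
                    )
                    calls[ref_pos] = SiteCall(site.label, query_pos, qc, status)
    return [calls[s.ref_position] for s in scheme.sites]


def _call_map(calls: Iterable[SiteCall]) -> dict[str, SiteCall]:
    return {c.site_label: c for c in calls}


def classify_counterion(
    calls: Sequence[SiteCall], scheme: ReferenceScheme
) -> tuple[str, str]:
    """(counterion_state, stability_prediction) from the counterion site call.

    E or D mapped to the counterion position -> charged -> monostable-like;
    any other residue -> uncharged -> bistable-like; a gap (or the X
    wildcard) -> indeterminate.
    """
    counterion_sites = scheme.sites_by_role(ROLE_COUNTERION)
    if not counterion_sites:
        raise SchemeError(f"scheme {scheme.scheme_id!r} has no counterion site")
    call = _call_map(calls)[counterion_sites[0].label]
    if call.status == STATUS_UNALIGNED or call.observed == "X":
        return INDETERMINATE, INDETERMINATE
    if call.observed in CHARGED_COUNTERION:
        return STATE_CHARGED, MONOSTABLE
    return STATE_UNCHARGED, BISTABLE


def profile_gprotein(
    calls: Sequence[SiteCall], scheme: ReferenceScheme
) -> tuple[dict[str, str], str, int, list[str]]:
    """Status of the four coupling pairs and the NPXXY motif.

    A pair is intact iff both member calls match; broken if a member
    mismatches or is unaligned while the other is informative; indeterminate
    only when both members are unaligned.  The deviation list names every
    non-matching site as ``LABEL:<residue>`` or ``LABEL:absent``.
    Returns (pair_status, motif_status, signaling_intact_count, deviations).
    """
    if not scheme.pairs or not scheme.motifs:
        raise SchemeError(
            f"scheme {scheme.scheme_id!r} lacks pair/motif rules"
        )
    cmap = _call_map(calls)
    by_pos = {s.ref_position: s for s in scheme.sites}
    deviations: list[str] = []

    def note_deviation(call: SiteCall) -> None:
        if call.status == STATUS_UNALIGNED:
            deviations.append(f"{call.site_label}:absent")
        elif call.status == STATUS_MISMATCH:
            deviations.append(f"{call.site_label}:{call.observed}")

    seen_labels: set[str] = set()
    pair_status: dict[str, str] = {}
    for pair in scheme.pairs:
        a, b = (cmap[m] for m in pair.member_labels)
        statuses = {a.status, b.status}
        if statuses == {STATUS_MATCH}:
            pair_status[pair.label] = PAIR_INTACT
        elif statuses == {STATUS_UNALIGNED}:
            pair_status[pair.label] = INDETERMINATE
        else:
            pair_status[pair.label] = PAIR_BROKEN
        for call in (a, b):
            if call.site_label not in seen_labels:
                seen_labels.add(call.site_label)
                note_deviation(call)

    motif = scheme.motifs[0]
    anchor_calls = [cmap[by_pos[p].label] for p in sorted(motif.anchors)]
    if all(c.status == STATUS_MATCH for c in anchor_calls):
        motif_status = PAIR_INTACT
    elif all(c.status == STATUS_UNALIGNED for c in anchor_calls):
        motif_status = INDETERMINATE
    else:
        motif_status = PAIR_BROKEN
    for call in anchor_calls:
        if call.site_label not in seen_labels:
            seen_labels.add(call.site_label)
            note_deviation(call)

    count = sum(1 for s in pair_status.values() if s == PAIR_INTACT)
    count += motif_status == PAIR_INTACT
    return pair_status, motif_status, count, deviations


def score_rlbp1(
    calls: Sequence[SiteCall], scheme: ReferenceScheme
) -> tuple[int, list[SiteCall]]:
    """Number of matches among the ten RLBP1-critical sites (unaligned
    counts as non-match), plus the per-site breakdown."""
    critical = scheme.sites_by_role(ROLE_RLBP1)
    if len(critical) != 10:
        raise SchemeError(
            f"scheme {scheme.scheme_id!r} defines {len(critical)} "
            "rlbp1_critical sites; exactly 10 required"
        )
    cmap = _call_map(calls)
    breakdown = [cmap[s.label] for s in critical]
    return sum(c.status == STATUS_MATCH for c in breakdown), breakdown


def build_profile(
    aln: PairwiseAlignment, scheme: ReferenceScheme
) -> FunctionalProfile:
    """Run every classifier the scheme supports on one aligned query."""
    calls = map_sites(aln, scheme)
    prof = FunctionalProfile(
        seq_id=aln.query_id, scheme_id=scheme.scheme_id, site_calls=calls
    )
    if scheme.sites_by_role(ROLE_COUNTERION):
        prof.counterion_state, prof.stability_prediction = classify_counterion(
            calls, scheme
        )
    if scheme.pairs and scheme.motifs:
        (
            prof.pair_status,
            prof.motif_status,
            prof.signaling_intact_count,
            prof.deviations,
        ) = profile_gprotein(calls, scheme)
    if scheme.sites_by_role(ROLE_RLBP1):
        prof.rlbp1_score, _ = score_rlbp1(calls, scheme)
    return prof


def profile_sequence(
    seq_id: str,
    seq: str,
    scheme: ReferenceScheme,
    sm: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> FunctionalProfile:
    """Align one query to the scheme reference and profile it."""
    aln = nw_align(
        seq,
        scheme.reference_seq,
        sm,
        gap_open,
        gap_extend,
        query_id=seq_id,
        ref_id=scheme.scheme_id,
    )
    return build_profile(aln, scheme)


# ---------------------------------------------------------------------------
# Reports


def profiles_to_frame(profiles: Sequence[FunctionalProfile]) -> pd.DataFrame:
    """One row per sequence; '.' for fields a scheme does not define."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "seq_id": p.seq_id,
            "scheme_id": p.scheme_id,
            "counterion_state": p.counterion_state or ".",
            "stability_prediction": p.stability_prediction or ".",
            "motif_status": p.motif_status or ".",
            "signaling_intact_count": (
                p.signaling_intact_count
                if p.signaling_intact_count is not None
                else "."
            ),
            "rlbp1_score": p.rlbp1_score if p.rlbp1_score is not None else ".",
            "deviations": ";".join(p.deviations) or ".",
        }
        for label, status in p.pair_status.items():
            row[f"pair:{label}"] = status
        for call in p.site_calls:
            row[f"site:{call.site_label}"] = call.status
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_to_json(profiles: Sequence[FunctionalProfile]) -> str:
    payload = []
    for p in profiles:
        payload.append(
            {
                "seq_id": p.seq_id,
                "scheme_id": p.scheme_id,
                "counterion_state": p.counterion_state,
                "stability_prediction": p.stability_prediction,
                "pair_status": p.pair_status,
                "motif_status": p.motif_status,
                "signaling_intact_count": p.signaling_intact_count,
                "rlbp1_score": p.rlbp1_score,
                "deviations": p.deviations,
                "site_calls": [
                    {
                        "site": c.site_label,
                        "query_position": c.query_position,
                        "observed": c.observed,
                        "status": c.status,
                    }
                    for c in p.site_calls
                ],
            }
        )
    return json.dumps(payload, indent=2)
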