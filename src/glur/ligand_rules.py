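"""Residue-rule engine for ligand and channel predictions.

The rules read fixed positions on the mature-GluA2 numbering scheme:

* Backbone binding — an iGluR can hold an amino-acid ligand at all only if
  Arg485 and an acidic residue at 705 (which fix the ligand's α-amino and
  α-carboxyl groups) are both present.
* Selectivity — positions 653/655 discriminate glutamate from glycine:
  glycine+threonine (and more broadly S/T at 653 with T at 655) marks
  glutamate binders; serine at 653 with a non-polar 655 marks glycine
  binders; an arginine at 653 (salt-bridged to Glu423) is a
  ctenophore-style glycine signature; a tyrosine at 653 occludes the
  binding pocket entirely.
* Channel character — a glutamine at the Q/R site (586) together with an
  acidic residue at 590 predicts calcium permeability and polyamine block
  (inward rectification).
* mGluRs — Arg78 and Lys409 (mGluR1 numbering) are required for glutamate
  binding; non-polar or acidic replacements at either mark the receptor
  glutamate-incompetent.

The cascade order (arginine-653 and tyrosine-653 rules before the
serine/threonine rules) is a package design choice: the two structurally
decisive signatures dominate. The order is visible in every call's
``rule_trace``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ConfigurationError
from .reference_map import SiteAssignment

ACIDIC = frozenset("DE")
#: default non-polar set used by the selectivity rules (config key)
NON_POLAR = frozenset("AVLIMFWPG")
#: residues read as "negative polarity" at 653/655 (candidate-glutamate rule)
NEGATIVE_POLARITY = frozenset("DE")

IGLUR_SITES = ("423", "485", "586", "590", "653", "655", "704", "705")
MGLUR_SITES = ("78", "409")

RULE_ORDER = ("R1", "R2", "R3", "R4", "R5", "R6", "R7", "R8", "R9")


@dataclass
class ResidueProfile:
    """Residue letters (or ``'-'``) at the scheme's diagnostic sites."""

    query_id: str
    residues: dict[str, str]
    scheme_name: str = ""

    @classmethod
    def from_assignment(cls, assignment: SiteAssignment) -> "ResidueProfile":
        return cls(
            query_id=assignment.query_id,
            residues=dict(assignment.residues),
            scheme_name=assignment.scheme_name,
        )

    def residue(self, label: str) -> str:
        return self.residues.get(str(label), "-")


@dataclass
class LigandCall:
    """Outcome of the selectivity cascade for one receptor."""

    category: str  # glutamate | glycine | candidate_glutamate | candidate_glycine
    #                | blocked_tyr653 | unclassified_phe | no_amino_acid | unknown
    confidence: str  # confident | candidate | none
    rule_trace: list[str] = field(default_factory=list)
    salt_bridge_423: bool | None = None  # annotated only for the Arg653 rule


@dataclass
class ChannelCall:
    """Q/R-site reading and the inward-rectification prediction."""

    qr_site: str
    acidic_590: bool
    rectification_flag: bool


def assess_backbone_binding(profile: ResidueProfile) -> bool:
    """True iff the amino-acid backbone can be fixed: Arg485 + acidic 705.

    A gap at either site fails the test.
    """
    return profile.residue("485") == "R" and profile.residue("705") in ACIDIC


def call_selectivity(
    profile: ResidueProfile,
    non_polar: frozenset = NON_POLAR,
    negative_polarity: frozenset = NEGATIVE_POLARITY,
    non_polar_site: str = "655",
) -> LigandCall:
    """Run the selectivity cascade; first matching rule wins.

    ``non_polar_site`` selects where the glycine rules' non-polar test reads:
    ``"655"`` (default), ``"704"``, or ``"either"`` — some Epsilon receptors
    appear to present the non-polar partner at 704 rather than 655.
    Gaps fail every residue test and fall through the cascade.
    """
    if non_polar_site not in {"655", "704", "either"}:
        raise ConfigurationError(f"invalid non_polar_site {non_polar_site!r}")
    r653 = profile.residue("653")
    r655 = profile.residue("655")
    r704 = profile.residue("704")

    def nonpolar_partner() -> bool:
        if non_polar_site == "655":
            return r655 in non_polar
        if non_polar_site == "704":
            return r704 in non_polar
        return r655 in non_polar or r704 in non_polar

    trace: list[str] = []

    trace.append("R1")
    if not assess_backbone_binding(profile):
        return LigandCall("no_amino_acid", "none", trace)
    trace.append("R2")
    if r653 == "R":
        return LigandCall(
            "glycine", "confident", trace, salt_bridge_423=profile.residue("423") == "E"
        )
    trace.append("R3")
    if r653 == "Y":
        return LigandCall("blocked_tyr653", "none", trace)
    trace.append("R4")
    if r653 == "S" and nonpolar_partner():
        return LigandCall("glycine", "confident", trace)
    trace.append("R5")
    if r653 in {"G", "S", "T"} and r655 == "T":
        return LigandCall("glutamate", "confident", trace)
    trace.append("R6")
    if r653 in negative_polarity and r655 in negative_polarity:
        return LigandCall("candidate_glutamate", "candidate", trace)
    trace.append("R7")
    if r653 == "G" and nonpolar_partner():
        return LigandCall("candidate_glycine", "candidate", trace)
    trace.append("R8")
    if r653 == "F" or r655 == "F":
        return LigandCall("unclassified_phe", "none", trace)
    trace.append("R9")
    return LigandCall("unknown", "none", trace)


def call_channel(profile: ResidueProfile) -> ChannelCall:
    """Read the Q/R site (586) and the acidic residue at 590."""
    qr = profile.residue("586")
    acidic = profile.residue("590") in ACIDIC
    return ChannelCall(qr_site=qr, acidic_590=acidic, rectification_flag=(qr == "Q" and acidic))


def call_mglur_binding(profile: ResidueProfile, non_polar: frozenset = NON_POLAR) -> str:
    """Classify an mGluR's glutamate-binding competence from Arg78/Lys409.

    Returns ``glutamate_competent``, ``glutamate_incompetent`` or ``unknown``.
    """
    r78 = profile.residue("78")
    r409 = profile.residue("409")
    if r78 == "R" and r409 == "K":
        return "glutamate_competent"
    disrupting = non_polar | ACIDIC
    if r78 in disrupting or r409 in disrupting:
        return "glutamate_incompetent"
    return "unknown"


def summarize_calls(
    calls: list[tuple[str, LigandCall, ChannelCall]],
    group_labels: dict[str, str] | None = None,
    groups: set[str] | None = None,
) -> dict:
    """Aggregate per-query calls into the count partition the analysis reports.

    ``group_labels`` maps query_id -> group; when ``groups`` is given, only
    queries whose label is in that set are counted.
    """
    if groups is not None and group_labels is not None:
        calls = [c for c in calls if group_labels.get(c[0], "") in groups]
    cats = Counter(lc.category for _, lc, _ in calls)
    summary = {
        "total": len(calls),
        "backbone_conserved": sum(
            1 for _, lc, _ in calls if lc.category != "no_amino_acid"
        ),
        "no_amino_acid": cats["no_amino_acid"],
        "acidic_590": sum(1 for _, _, cc in calls if cc and cc.acidic_590),
        "qr_glutamine": sum(1 for _, _, cc in calls if cc and cc.qr_site == "Q"),
        "rectifying": sum(1 for _, _, cc in calls if cc and cc.rectification_flag),
        "confident": cats["glutamate"] + cats["glycine"],
        "glutamate": cats["glutamate"],
        "glycine": cats["glycine"],
        "candidate_glutamate": cats["candidate_glutamate"],
        "candidate_glycine": cats["candidate_glycine"],
        "blocked_tyr653": cats["blocked_tyr653"],
        "unclassified_phe": cats["unclassified_phe"],
        "unknown": cats["unknown"],
    }
    return summary
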