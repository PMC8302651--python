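"""Metaweb construction from the trophic scheme's feeding knowledge.

The metaweb holds every *potential* trophic interaction of the study
system.  Feeding knowledge is data (per-group whitelists/blacklists in the
scheme fixture); the ecological constraint rules are code, so the same
machinery can build metawebs for other systems:

* size rule — consumers take prey of equal or smaller body-size rank,
  except consumers flagged ``size_exception`` (animal parasites and
  omnivore nematodes can attack larger prey);
* scale rule — macroorganisms and microorganisms do not interact, except
  consumers flagged ``cross_scale_feeder`` (e.g. microbivorous mites and
  collembola grazing on bacteria or fungal hyphae);
* habitat rule — strict endoparasites (plant-pathogen protists) are not
  prey of free-living consumers;
* blacklist — explicitly avoided prey (e.g. fungivores reject arbuscular
  mycorrhizal fungi, which lack the edible extraradical biomass of
  saprotrophs and ectomycorrhizal fungi).

Edges point prey -> consumer (energy flow).  Resource nodes (sunlight,
organic matter, plants) anchor basal groups structurally and never have
incoming links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Metaweb, TrophicScheme, RESOURCE_NODES


@dataclass(frozen=True)
class RuleViolation:
    prey: str
    consumer: str
    rule: str  # 'size' | 'scale' | 'habitat' | 'blacklist'
    message: str


def _link_violations(prey: str, consumer: str, scheme: TrophicScheme) -> list[RuleViolation]:
    g = scheme.groups
    out: list[RuleViolation] = []
    if (g.at[prey, "size_rank"] > g.at[consumer, "size_rank"]
            and not g.at[consumer, "size_exception"]):
        out.append(RuleViolation(prey, consumer, "size",
                                 f"{consumer} smaller than prey {prey}"))
    if (g.at[prey, "organism_scale"] != g.at[consumer, "organism_scale"]
            and not g.at[consumer, "cross_scale_feeder"]):
        out.append(RuleViolation(prey, consumer, "scale",
                                 "macro/micro organisms do not interact"))
    if g.at[prey, "endoparasite"] and not g.at[consumer, "endoparasite"]:
        out.append(RuleViolation(prey, consumer, "habitat",
                                 f"endoparasite {prey} is not free-living prey"))
    if prey in scheme.avoid_of(consumer):
        out.append(RuleViolation(prey, consumer, "blacklist",
                                 f"{consumer} avoids {prey}"))
    return out


def build_metaweb(scheme: TrophicScheme, resource_nodes: bool = True) -> Metaweb:
    """Build the group-level metaweb from the scheme's feeding whitelists.

    A candidate link (prey -> consumer) from a consumer's whitelist is
    retained only if it passes every constraint rule.  Resource links are
    attached from the ``resource_links`` traits.
    """
    groups = scheme.group_ids
    nodes = (list(RESOURCE_NODES) if resource_nodes else []) + groups
    adj = pd.DataFrame(0.0, index=pd.Index(nodes, name="prey"), columns=nodes)
    for consumer in groups:
        for prey in scheme.prey_of(consumer):
            if prey == consumer:
                raise ValidationError(f"self-link declared for {consumer!r}")
            if not _link_violations(prey, consumer, scheme):
                adj.at[prey, consumer] = 1.0
        if resource_nodes:
            for res in scheme.resources_of(consumer):
                adj.at[res, consumer] = 1.0
    return Metaweb(adjacency=adj, resolution="group",
                   resource_nodes=tuple(RESOURCE_NODES) if resource_nodes else ())


def validate_metaweb(web: Metaweb, scheme: TrophicScheme) -> list[RuleViolation]:
    """Check every group-to-group link of a metaweb against the rules.

    Returns the (possibly empty) list of violations; violations are data,
    not exceptions.  Resource links are structural and not checked.
    """
    if web.resolution != "group":
        raise ValidationError("only group-resolution metawebs are rule-checked")
    out: list[RuleViolation] = []
    known = set(scheme.group_ids)
    for prey, consumer in web.links():
        if prey in web.resource_nodes:
            continue
        if prey not in known or consumer not in known:
            raise ValidationError(f"link ({prey!r}, {consumer!r}) references unknown group")
        out.extend(_link_violations(prey, consumer, scheme))
    return out


def aggregate_metaweb(web: Metaweb, scheme: TrophicScheme) -> Metaweb:
    """Aggregate a group metaweb to the 9 broad trophic classes.

    Classes k -> l are linked iff some member group pair is linked; the
    class web is binary.  Resource nodes are carried over unchanged.
    """
    g2c = scheme.group_to_class()
    classes = scheme.class_ids
    resources = [r for r in web.resource_nodes if r in web.adjacency.index]
    nodes = resources + classes
    adj = pd.DataFrame(0.0, index=pd.Index(nodes, name="prey"), columns=nodes)
    for prey, consumer in web.links():
        src = prey if prey in resources else g2c[prey]
        adj.at[src, g2c[consumer]] = 1.0
    return Metaweb(adjacency=adj, resolution="class", resource_nodes=tuple(resources))


def strip_resource_nodes(web: Metaweb) -> Metaweb:
    """Remove resource nodes and their incident links; idempotent."""
    keep = [n for n in web.adjacency.index if n not in web.resource_nodes]
    adj = web.adjacency.loc[keep, keep]
    return Metaweb(adjacency=adj.copy(), resolution=web.resolution, resource_nodes=())
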