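"""Default region label sets.

The pipeline operates on three volumetric networks:

* intrathalamic — 50 thalamic nuclei (25 per hemisphere, FreeSurfer-style
  thalamic segmentation labels);
* thalamocortical — the 50 nuclei against the 68 Desikan–Killiany cortical
  parcels (34 per hemisphere);
* thalamosubcortical — the 50 nuclei against 12 subcortical structures
  (6 per hemisphere; the thalamus itself is excluded because its nuclei are
  the seed set).

Labels are plain strings of the form ``L_<abbrev>`` / ``R_<abbrev>`` so a
feature table can carry one numeric column per region.
"""

from __future__ import annotations

THALAMIC_NUCLEI: tuple[str, ...] = (
    "MDm", "MDl", "CeM", "Re", "AV", "Pt", "CM", "Pf", "CL", "Pc",
    "LD", "LP", "LGN", "MGN", "LSg", "PuI", "PuL", "PuA", "PuM", "VPL",
    "VM", "VLa", "VLp", "VA", "VAmc",
)

DESIKAN_KILLIANY: tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal",
    "temporalpole", "transversetemporal",
)

SUBCORTICAL: tuple[str, ...] = (
    "Accumbens", "Amygdala", "Caudate", "Hippocampus", "Pallidum", "Putamen",
)

HEMISPHERES: tuple[str, str] = ("L", "R")


def _bilateral(names: tuple[str, ...]) -> list[str]:
    return [f"{h}_{n}" for h in HEMISPHERES for n in names]


def thalamic_labels(hemisphere: str | None = None) -> list[str]:
    """The 50 thalamic nucleus labels, or the 25 of one hemisphere."""
    if hemisphere is None:
        return _bilateral(THALAMIC_NUCLEI)
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {hemisphere!r}")
    return [f"{hemisphere}_{n}" for n in THALAMIC_NUCLEI]


def cortical_labels(hemisphere: str | None = None) -> list[str]:
    """The 68 Desikan–Killiany cortical labels, or the 34 of one hemisphere."""
    if hemisphere is None:
        return _bilateral(DESIKAN_KILLIANY)
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {hemisphere!r}")
    return [f"{hemisphere}_{n}" for n in DESIKAN_KILLIANY]


def subcortical_labels() -> list[str]:
    """The 12 subcortical volume labels (6 per hemisphere)."""
    return _bilateral(SUBCORTICAL)


def all_region_labels() -> list[str]:
    """Thalamic + cortical + subcortical labels, in canonical order (130)."""
    return thalamic_labels() + cortical_labels() + subcortical_labels()


NETWORKS: dict[str, tuple[str, str | None]] = {
    # name -> (seed set, partner set); partner None => unipartite
    "intrathalamic": ("thalamic", None),
    "thalamocortical": ("thalamic", "cortical"),
    "thalamosubcortical": ("thalamic", "subcortical"),
}

_SET_GETTERS = {
    "thalamic": thalamic_labels,
    "cortical": cortical_labels,
    "subcortical": subcortical_labels,
}


def network_node_sets(name: str) -> tuple[list[str], list[str] | None]:
    """Node sets for a named network: (setA, setB) with setB None if unipartite."""
    try:
        a, b = NETWORKS[name]
    except KeyError:
        raise ValueError(f"unknown network {name!r}; choose from {sorted(NETWORKS)}") from None
    return _SET_GETTERS[a](), (None if b is None else _SET_GETTERS[b]())
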