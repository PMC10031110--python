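"""Desikan-Killiany cortical parcellation labels.

The standard FreeSurfer ``aparc`` atlas has 34 cortical regions per
hemisphere.  Canonical column names are ``<hemi>_<region>_thickness`` with
``hemi`` in ``{lh, rh}``, matching the headers produced by
``aparcstats2table``.
"""

from __future__ import annotations

DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

HEMIS: tuple[str, str] = ("lh", "rh")

#: Regions of the posterior cortex (occipital + parietal and neighbours) where
#: thinning with advancing pubertal stage is expected; used as the default
#: location of planted thickness effects in the synthetic cohort.
POSTERIOR_REGIONS: tuple[str, ...] = (
    "cuneus",
    "lateraloccipital",
    "lingual",
    "pericalcarine",
    "inferiorparietal",
    "superiorparietal",
    "precuneus",
)


def region_columns() -> list[str]:
    """All 68 canonical thickness column names, left hemisphere first."""
    return [f"{h}_{r}_thickness" for h in HEMIS for r in DK_REGIONS]


def parse_region_column(name: str) -> tuple[str, str]:
    """Split ``lh_cuneus_thickness`` into ``("lh", "cuneus")``.

    Raises ``ValueError`` for names not in the canonical form.
    """
    parts = name.split("_")
    if len(parts) < 3 or parts[0] not in HEMIS or parts[-1] != "thickness":
        raise ValueError(f"not a canonical thickness column: {name!r}")
    region = "_".join(parts[1:-1])
    if region not in DK_REGIONS:
        raise ValueError(f"unknown Desikan-Killiany region: {region!r}")
    return parts[0], region
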