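"""Region definitions for the 76-node Desikan-Killiany parcellation.

The node set comprises 38 cortical/subcortical regions per hemisphere,
averaged within parcels to one time course per region. Labels use the
hemisphere prefix ``L_`` / ``R_`` plus the conventional abbreviation.
"""

from __future__ import annotations

# (full name, abbreviation), one entry per bilateral region
DESIKAN_REGIONS: list[tuple[str, str]] = [
    ("Banks superior temporal sulcus", "BANK"),
    ("Caudal anterior cingulate cortex", "CauACC"),
    ("Caudal middle frontal gyrus", "CauMFG"),
    ("Cuneus cortex", "CUN"),
    ("Fusiform gyrus", "FFG"),
    ("Inferior parietal cortex", "IPC"),
    ("Inferior temporal gyrus", "ITG"),
    ("Isthmus-cingulate cortex", "ICC"),
    ("Lateral occipital cortex", "LatOC"),
    ("Lateral orbitalfrontal cortex", "LatOFC"),
    ("Lingual gyrus", "LING"),
    ("Medial orbitalfrontal cortex", "MedOFC"),
    ("Middle temporal gyrus", "MTG"),
    ("Parahippocampal gyrus", "PHG"),
    ("Paracentral lobule", "PCL"),
    ("Pars opercularis", "ParsOPE"),
    ("Pars orbitalis", "ParsORB"),
    ("Pars triangularis", "ParsTRI"),
    ("Pericalcarine cortex", "PCAL"),
    ("Postcentral gyrus", "PoCG"),
    ("Posterior cingulate cortex", "PCC"),
    ("Precentral gyrus", "PreCG"),
    ("Precuneus gyrus", "PCUN"),
    ("Rostral anterior cingulate cortex", "RosACC"),
    ("Rostral middle frontal gyrus", "RosMFG"),
    ("Superior frontal gyrus", "SFG"),
    ("Superior parietal cortex", "SPC"),
    ("Superior temporal gyrus", "STG"),
    ("Supramarginal gyrus", "SMG"),
    ("Transverse temporal cortex", "TTC"),
    ("Insula", "INS"),
    ("Thalamus", "THA"),
    ("Caudate", "CAU"),
    ("Putamen", "PUT"),
    ("Pallidum", "PAL"),
    ("Hippocampus", "HIP"),
    ("Amygdala", "AMYG"),
    ("Accumbens", "ACCU"),
]

N_REGIONS = 2 * len(DESIKAN_REGIONS)  # 76


def default_region_labels(n_regions: int = N_REGIONS) -> list[str]:
    """Region labels for an ``n_regions``-node parcellation.

    For the default 76 nodes these are the bilateral Desikan-Killiany
    abbreviations (left hemisphere block first). Other sizes get generic
    ``ROI_001`` style labels so reduced synthetic problems stay usable.
    """
    if n_regions == N_REGIONS:
        return [f"L_{abbr}" for _, abbr in DESIKAN_REGIONS] + [
            f"R_{abbr}" for _, abbr in DESIKAN_REGIONS
        ]
    return [f"ROI_{i + 1:03d}" for i in range(n_regions)]
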