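"""White-matter ROI vocabulary and skeleton voxel constants.

The regional outcomes follow the Johns Hopkins ICBM-DTI-81 white-matter
label atlas as summarized on the TBSS skeleton: 24 bilateral (or
mid-sagittal) tract ROIs plus the full-skeleton average, giving the 25
outcomes analysed per DTI metric.  Two additional skeleton summaries are
carried alongside: the "core" (skeleton voxels inside the atlas labels)
and the "periphery" (skeleton voxels outside them).
"""

from __future__ import annotations

# 24 tract ROIs (hemisphere-combined), canonical abbreviations
TRACTS: tuple[str, ...] = (
    "ACR",   # anterior corona radiata
    "ALIC",  # anterior limb of internal capsule
    "BCC",   # body of corpus callosum
    "CC",    # corpus callosum (full)
    "CGC",   # cingulum, cingulate gyrus part
    "CGH",   # cingulum, perihippocampal part
    "CR",    # corona radiata (full)
    "CST",   # cortico-spinal tract
    "EC",    # external capsule
    "FX",    # fornix
    "FXST",  # fornix / stria terminalis
    "GCC",   # genu of corpus callosum
    "IC",    # internal capsule (full)
    "IFO",   # inferior fronto-occipital fasciculus
    "PCR",   # posterior corona radiata
    "PLIC",  # posterior limb of internal capsule
    "PTR",   # posterior thalamic radiation
    "RLIC",  # retrolenticular limb of internal capsule
    "SCC",   # splenium of corpus callosum
    "SCR",   # superior corona radiata
    "SFO",   # superior fronto-occipital fasciculus
    "SLF",   # superior longitudinal fasciculus
    "SS",    # sagittal stratum
    "UNC",   # uncinate fasciculus
)

AVERAGE = "Average"
CORE = "Core"
PERIPHERY = "Periphery"

#: The 25 regional outcomes entering every regression battery
#: (full-skeleton average + 24 tracts).
ROI_OUTCOMES: tuple[str, ...] = (AVERAGE,) + TRACTS

#: Skeleton summaries usable as global covariates.
SKELETON_SUMMARIES: tuple[str, ...] = (AVERAGE, CORE, PERIPHERY)

#: Full label vocabulary accepted in ROI-measure tables.
ROI_VOCABULARY: tuple[str, ...] = ROI_OUTCOMES + (CORE, PERIPHERY)

METRICS: tuple[str, ...] = ("FA", "MD", "RD", "AD")

# Voxel counts of the standard skeleton template used for the
# average/core/periphery decomposition.
V_TOTAL = 112_889   # entire skeleton
V_CORE = 31_742     # skeleton voxels inside the atlas labels
V_PERIPHERY = 81_147  # V_TOTAL - V_CORE

assert V_TOTAL - V_CORE == V_PERIPHERY

N_ROI_TESTS = len(ROI_OUTCOMES)  # 25; Bonferroni divisor per metric
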