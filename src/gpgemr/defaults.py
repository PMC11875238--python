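"""Default analysis thresholds, surfaced in one place.

Every gate is an explicit parameter of the function that applies it; these
constants only provide the defaults used by the pipeline and CLI.
"""

#: genome-wide significance for cis-pQTL instrument selection
PQTL_P_THRESHOLD = 5e-8
#: cis window around the encoding gene, in base pairs
CIS_WINDOW_BP = 250_000
#: maximum pairwise r^2 among instruments after LD pruning
R2_MAX = 0.01
#: false discovery rate for the protein-level MR screen
FDR_Q = 0.05
#: Bonferroni threshold for the gene x tissue TWAS screen
GPGE_BONFERRONI = 2.03e-7
#: TWAS p-value gate for a tissue to serve as a drug-MR instrument
INSTRUMENT_P_THRESHOLD = 0.05
#: PP.H4 decision threshold, expression-trait colocalization
COLOC_PP4_EQTL = 0.8
#: PP.H4 decision threshold, protein-trait colocalization
COLOC_PP4_PQTL = 0.7
#: alpha for switching fixed-effects IVW to random-effects on Cochran's Q
HETEROGENEITY_ALPHA = 0.05
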