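"""Tunable constants shared across the pipeline.

Values with a stated provenance in the tool's method (point scheme, window
sizes, e-value cutoffs, distances) are contract defaults; changing them
changes the contract, so they live here rather than being buried in call
sites.
"""

# --- local alignment scoring (blastn-like) ---------------------------------
MATCH = 1
MISMATCH = -2
GAP_OPEN = -5        # cost of the first gap residue
GAP_EXTEND = -2      # cost of each further gap residue

# Karlin-Altschul surrogate constants for ungapped-style bit scores.
# Calibrated so a 24 bp exact hit against a ~1e5..1e8 bp genome lands near
# the 1e-5 significance boundary while a 20 bp hit does not.
KA_LAMBDA = 1.28
KA_K = 0.46

# --- seeding ---------------------------------------------------------------
KMER_K = 12          # word size of the genome index and of search seeds
SEED_BAND = 10       # seeds within +-band of a diagonal are chained

# --- FST evaluation --------------------------------------------------------
EVALUE_SIGNIFICANT = 1e-3    # category 0/1 vs 2 boundary
EVALUE_RATIO_LIMIT = 1e10    # discard hits this much worse than region best
MAX_CAT1_PER_REGION = 3
REGION_OVERLAP = 30          # bp of query overlap joining hits into a region
MERGE_DISTANCE = 1000        # predictions closer than this are one insertion
FST_MIN_HIT_LEN = 24

# --- paralog grouping ------------------------------------------------------
FLANK_LEN = 400
FLANK_IDENTITY_MIN = 0.79    # strictly-greater-than threshold

# --- primer arithmetic -----------------------------------------------------
MIN_PRIMER_LEN = 18
MAX_PRIMER_LEN = 30
TM_TOLERANCE = 3.0           # max |Tm - target| accepted by elongation
MAX_RUN = 5                  # homopolymer runs longer than this fail
GC_MIN = 40.0
GC_MAX = 60.0
POINTS_GC_CLAMP = 8
POINTS_NO_RUNS = 4
POINTS_GC_OK = 2
POINTS_NO_HAIRPIN = 1
MIN_POINTS = 15              # retention threshold for candidates
MISMATCH_WINDOW = 5          # 3'-terminal columns credited with mismatches

# --- design methods --------------------------------------------------------
EVALUE_DESIGN = 1e-5         # zone BLAST cutoff for method choice / paralogs
MIN_UNIQUE_SEGMENT = 100     # unique part this long routes to standard method
MIN_PARALOG_HIT_LEN = 50
STD_WINDOW = 80
STD_WINDOW_FALLBACK = 110
STD_OVERLAP = 30
TM_STEPS = (0.0, -0.4, 0.4, -0.8, 0.8, -1.2, 1.2)
MSA_WINDOW = 220
MSA_OVERLAP = 30
MAX_PARALOG_COLUMNS = 200    # cap on 3'-end candidate columns per zone
MIN_FALLBACK_COLUMNS = 20    # pad with zero-mismatch columns below this

# --- designer defaults -----------------------------------------------------
DEFAULT_MIN_DIST = 300
DEFAULT_MAX_DIST = 800
DIST_BOUNDS = (100, 1500)
MIN_RANGE_PER_SIDE = 100
DEFAULT_TM = 60.5
TM_BOUNDS = (50.0, 72.0)

REPORT_SCHEMA_VERSION = 1
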