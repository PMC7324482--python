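"""Small published reference inputs for the ZFP36L2 / Ikzf2 analysis.

These are fixed, citable quantities from the forced-ZFP36L2-expression
screen in murine CD4+ T cells that this package re-implements: the
EMSA probe sequences covering the three AREs of the murine *Ikzf2*
3'UTR, the screen's headline contingency counts, and the *Ikzf2* mRNA
half-lives measured by actinomycin-D chase.  They serve as verification
inputs; none of them is required to run the pipeline on new data.
"""

#: RNA probe sequences, each spanning exactly one ARE of the murine
#: Ikzf2 3'UTR (as used in gel-shift binding assays).
IKZF2_ARE_PROBES: dict[str, str] = {
    "ARE1": "UUUACUAGGGCUAUUUAUUCCACUAUUU",
    "ARE2": "AAGGAUAUUUAUUUCUGAAUGAGGUAAAUAAGUU",
    "ARE3": "UUAUUCAUAUUUAUAUGUAGUGUGUUCU",
}

#: Headline counts of the forced-expression screen: of 24,941 detected
#: genes, 4,368 carried the ARE heptamer in their 3'UTR; of the 620
#: downregulated genes, 233 carried it.
SCREEN_REFERENCE_COUNTS: dict[str, int] = {
    "n_detected": 24941,
    "n_detected_are": 4368,
    "n_down": 620,
    "n_down_are": 233,
}

#: Ikzf2 mRNA half-lives (hours) from actinomycin-D chase in iTregs,
#: mock- versus ZFP36L2-transduced.  Used as simulation ground truth.
REFERENCE_HALF_LIVES_H: dict[str, float] = {
    "mock": 3.01,
    "zfp36l2": 0.33,
}
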