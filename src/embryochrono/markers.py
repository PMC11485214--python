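"""Cell-cycle marker gene lists used for S-/M-phase scoring.

Mouse gene symbols for the synthesis-phase and mitosis-phase programs;
``AB349069`` is a cDNA clone identifier kept verbatim as it appears in
expression references.
"""

S_PHASE_GENES: tuple[str, ...] = (
    "Pcna",
    "Rrm2",
    "Mcm5",
    "Mcm6",
    "Mcm4",
    "Ung",
    "Mcm7",
    "Mcm2",
    "Uhrf1",
    "Orc6",
    "Tipin",
)

M_PHASE_GENES: tuple[str, ...] = (
    "Mki67",
    "Cenpf",
    "Top2a",
    "Smc4",
    "Ube2c",
    "Ccnb1",
    "Cdk1",
    "Arl6ip1",
    "Ankrd11",
    "Hmmr",
    "Cenpa",
    "Tpx2",
    "Aurka",
    "AB349069",
    "Kif4",
    "Kif2c",
    "Bub1b",
    "Ccna2",
    "Kif23",
    "Kif20a",
    "Sgol2a",
    "Smc2",
    "Kif11",
    "Cdca2",
    "Incenp",
    "Cenpe",
)
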