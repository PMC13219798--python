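"""Physical constants and the study taxonomy shared across modules."""

#: Density of calcite, pg per cubic micron.
RHO_CALCITE = 2.7

#: Mass fraction of carbon in CaCO3 (12.011 / 100.087).
CARBON_FRACTION_CALCITE = 12.011 / 100.087

#: The five target taxa, by the names used throughout the tables.
SMALL_GEPHYROCAPSA = "small Gephyrocapsa"
LARGE_GEPHYROCAPSA = "large Gephyrocapsa"
HELICOSPHAERA = "Helicosphaera spp."
CALCIDISCUS = "Calcidiscus spp."
C_PELAGICUS = "Coccolithus pelagicus"

TARGET_TAXA = (
    SMALL_GEPHYROCAPSA,
    LARGE_GEPHYROCAPSA,
    HELICOSPHAERA,
    CALCIDISCUS,
    C_PELAGICUS,
)

#: PIC/POC functional group of each target taxon.  Gephyrocapsa taxa allocate
#: proportionally more fixed carbon to organic matter (low PIC/POC); the three
#: heavily calcified genera form the high PIC/POC group.
PIC_POC_GROUP = {
    SMALL_GEPHYROCAPSA: "low",
    LARGE_GEPHYROCAPSA: "low",
    HELICOSPHAERA: "high",
    CALCIDISCUS: "high",
    C_PELAGICUS: "high",
}

LOW_GROUP_TAXA = tuple(t for t in TARGET_TAXA if PIC_POC_GROUP[t] == "low")
HIGH_GROUP_TAXA = tuple(t for t in TARGET_TAXA if PIC_POC_GROUP[t] == "high")
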