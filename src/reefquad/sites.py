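"""The monitoring program's default site roster.

Six shallow-water (3-10 m) localities around Carrie Bow Cay, Belize:
three patch-type reefs (two patch reefs plus a fringing reef grouped with
them) and three forereefs, two of which were surveyed on fixed transects.
"""

STUDY_SITES = (
    "CBC Lagoon Reef",
    "Curlew Patch Reef",
    "CBC House Reef",
    "CBC Reef Central",
    "South Reef Central",
    "Tobacco Reef",
)

STUDY_REEF_TYPES = {
    "CBC Lagoon Reef": "patch",
    "Curlew Patch Reef": "patch",
    "CBC House Reef": "patch",
    "CBC Reef Central": "forereef",
    "South Reef Central": "forereef",
    "Tobacco Reef": "forereef",
}

FIXED_TRANSECT_SITES = ("CBC Reef Central", "South Reef Central")

STUDY_YEARS = (2014, 2016, 2017, 2018, 2019)
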