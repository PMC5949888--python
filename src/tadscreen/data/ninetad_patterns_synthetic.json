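{
  "description": "Synthetic reconstruction of the four nine-residue TAD motif regular expressions. The originally published patterns are distributed through a web resource and are not redistributable here; these four nine-column variants encode the published consensus (a bulky-hydrophobic pair embedded in a polar/acidic, arginine/lysine-poor context) and serve as documented stand-ins. Each pattern spans exactly nine residue columns.",
  "synthetic": true,
  "patterns": [
    "[MDENQSTYCPGA][ILVFWMAY][ILVFWMAY]..[ILVFWMAY][^KR][^KR].",
    ".[ILVFWMAY].[ILVFWMAY][ILVFWMAY]..[DE].",
    "[DE]..[ILVFWMAY][ILVFWMAY].[ILVFWMAY]..",
    ".[DE].[ILVFWMAY].[ILVFWMAY]..[ILVFWMAY]"
  ]
}
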