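{
  "α": "A", "β": "B", "γ": "G", "δ": "D", "ε": "E", "ζ": "Z",
  "η": "H", "θ": "TH", "ι": "I", "κ": "K", "λ": "L", "μ": "M",
  "ν": "N", "ξ": "X", "ο": "O", "π": "P", "ρ": "R", "σ": "S",
  "τ": "T", "υ": "U", "φ": "PH", "χ": "CH", "ψ": "PS", "ω": "O",
  "Α": "A", "Β": "B", "Γ": "G", "Δ": "D", "Κ": "K", "Λ": "L", "Μ": "M"
}
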