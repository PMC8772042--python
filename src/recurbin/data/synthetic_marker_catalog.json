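{
  "name": "synthetic-scg-20",
  "sets": [
    ["SCG001", "SCG002", "SCG003", "SCG004", "SCG005"],
    ["SCG006", "SCG007", "SCG008", "SCG009", "SCG010"],
    ["SCG011", "SCG012", "SCG013", "SCG014", "SCG015"],
    ["SCG016", "SCG017", "SCG018", "SCG019", "SCG020"]
  ]
}
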