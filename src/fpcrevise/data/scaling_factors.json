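{
  "provenance": "Default linear-regression shielding-to-shift factors of the conventional magnitude for mPW1PW91-family GIAO levels with PCM chloroform. Replace with the repository entry for your exact level of theory; the convention is delta = (intercept - sigma_iso) / (-slope).",
  "level": "mPW1PW91/6-311+G(d,p)//B3LYP/6-31+G(d,p), PCM(CHCl3) [default]",
  "factors": {
    "C": {"slope": -1.0522, "intercept": 186.5242},
    "H": {"slope": -1.0781, "intercept": 31.8723}
  }
}
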