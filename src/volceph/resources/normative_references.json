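{
  "version": 1,
  "source": "reported normative aesthetic distributions, gender-stratified (n=26 female, n=20 male)",
  "references": {
    "female": {
      "mean_volumes_mm3": {
        "malar": 283005,
        "maxillary": 212433,
        "mandibular": 202279,
        "chin": 34340
      },
      "shares": {
        "malar": 38.7,
        "maxillary": 29.0,
        "mandibular": 27.6,
        "chin": 4.7
      },
      "mm_ratio": 1.05,
      "flags": []
    },
    "male": {
      "mean_volumes_mm3": {
        "malar": 300436,
        "maxillary": 230526,
        "mandibular": 242905,
        "chin": 49444
      },
      "shares": {
        "malar": 37.0,
        "maxillary": 26.0,
        "mandibular": 30.0,
        "chin": 6.0
      },
      "mm_ratio": 0.87,
      "flags": [
        "shares sum to 99% as reported",
        "malar and maxillary shares are inconsistent with the reported mean volumes (computed 36.5% and 28.0%)",
        "reported mm_ratio 0.87 equals 26/30 from the inconsistent share line; the volume-derived ratio is 0.95"
      ]
    }
  }
}
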