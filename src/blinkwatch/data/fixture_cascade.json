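{
  "comment": "Hand-built single-stage center-surround cascade: accepts a 16x16 window whose central 8x8 is markedly darker than its surround (a pupil/iris disc). Rect weights satisfy sum(weight*area)=0 so any constant window scores exactly 0.",
  "window_w": 16,
  "window_h": 16,
  "stages": [
    {
      "stage_threshold": 0.5,
      "features": [
        {
          "rects": [[0, 0, 16, 16, 1.0], [4, 4, 8, 8, -4.0]],
          "threshold": 0.5,
          "left_val": -1.0,
          "right_val": 1.0
        }
      ]
    }
  ]
}
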