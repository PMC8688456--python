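{
 "eq2_order6": {
  "form": "linear",
  "names": [
   "alpha",
   "beta"
  ],
  "constants": [
   -1.8245,
   96.5461
  ],
  "r_squared_printed": 0.7903,
  "source_label": "linear fit, order-6 alkanes"
 },
 "eq3_order6": {
  "form": "log_trig",
  "names": [
   "alpha",
   "beta",
   "alpha1",
   "alpha2",
   "alpha3",
   "alpha4",
   "alpha5",
   "alpha6"
  ],
  "constants": [
   2.7173,
   -0.203,
   24.5237,
   3.5331,
   0.4679,
   -6.7879,
   -0.9061,
   18.1828
  ],
  "r_squared_printed": 1.0,
  "source_label": "log-trig fit, order-6 alkanes"
 },
 "eq4_pn": {
  "form": "series_loglinear",
  "names": [
   "alpha",
   "beta",
   "alpha1",
   "alpha2",
   "alpha3",
   "alpha4"
  ],
  "constants": [
   1.5911,
   20.9101,
   41.6488,
   1.2703,
   0.0429,
   0.5061
  ],
  "r_squared_printed": 0.9999,
  "source_label": "normal-alkane series (P_n)"
 },
 "eq5_bn2": {
  "form": "series_loglinear",
  "names": [
   "alpha",
   "beta",
   "alpha1",
   "alpha2",
   "alpha3",
   "alpha4"
  ],
  "constants": [
   1.2125,
   23.5857,
   40.7654,
   1.3216,
   0.03559,
   0.3998
  ],
  "r_squared_printed": 0.9996,
  "source_label": "2-methyl series (B_{n,2})"
 },
 "eq6_bn3": {
  "form": "series_loglinear",
  "names": [
   "alpha",
   "beta",
   "alpha1",
   "alpha2",
   "alpha3",
   "alpha4"
  ],
  "constants": [
   2.2207,
   15.9874,
   9.8662,
   1.3271,
   0.0613,
   -0.8074
  ],
  "r_squared_printed": 0.9999,
  "source_label": "2,2-dimethyl series (B_{n,3})"
 },
 "eq7_en": {
  "form": "series_loglinear",
  "names": [
   "alpha",
   "beta",
   "alpha1",
   "alpha2",
   "alpha3",
   "alpha4"
  ],
  "constants": [
   1.0404,
   -360.7375,
   4.28,
   1.0802,
   63.5399,
   -499.3487
  ],
  "r_squared_printed": 0.9751,
  "source_label": "high-conduction series (E_n)"
 },
 "prop22_en": {
  "form": "quad_conduction",
  "names": [
   "alpha",
   "beta",
   "gamma",
   "lambda"
  ],
  "constants": [
   0.4444444444444444,
   3.44857532,
   -14.95083692,
   18.25213877
  ],
  "r_squared_printed": 0.9924,
  "alpha_exact": "4/9",
  "source_label": "fitted c(E_n) approximation"
 }
}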