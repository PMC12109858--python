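skill,speed_variance,speed_sd,accuracy_variance,accuracy_sd
dotComparison,0.7153,0.8458,1081.714,32.8894
subitizing,0.0286,0.169,1707.3046,41.3195
numberRecognition,0.6335,0.796,1498.5401,38.711
numberComparison,0.1417,0.3764,1723.6636,41.517
mentalNumberLine,0.8028,0.896,882.3046,29.7036
numberLine,0.4742,0.6886,622.0535,24.941
counting,0.4281,0.6543,1519.2679,38.9778
numberSequence,0.4347,0.6593,743.6749,27.2704
addition,0.4045,0.636,1682.6616,41.0203
subtraction,0.714,0.845,1320.8056,36.3429
multiplication,0.5255,0.7249,940.8224,30.6728
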