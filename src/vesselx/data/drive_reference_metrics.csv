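image_id,sensitivity,specificity,accuracy,precision
retina_01,0.689029,0.983848,0.957543,0.806914
retina_02,0.681326,0.98826,0.956828,0.868788
retina_03,0.662299,0.982472,0.950555,0.807091
retina_04,0.612176,0.994229,0.959083,0.914874
retina_05,0.625776,0.99155,0.957283,0.884459
retina_06,0.619286,0.98656,0.950812,0.832454
retina_07,0.645363,0.982846,0.952006,0.790952
retina_08,0.646095,0.981693,0.952819,0.768638
retina_09,0.64762,0.985057,0.95771,0.792622
retina_10,0.619679,0.989112,0.958707,0.836174
retina_11,0.663699,0.98082,0.952431,0.772854
retina_12,0.690874,0.979726,0.954785,0.763055
retina_13,0.560464,0.990786,0.948715,0.868271
retina_14,0.751659,0.969751,0.952118,0.686101
retina_15,0.714534,0.973168,0.954658,0.672419
retina_16,0.680373,0.984199,0.956767,0.810371
retina_17,0.665984,0.977015,0.950761,0.727612
retina_18,0.703259,0.97927,0.957401,0.744855
retina_19,0.804903,0.986169,0.971133,0.840365
retina_20,0.69116,0.983526,0.962026,0.769065
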