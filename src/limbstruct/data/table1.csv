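element,side,location_pct,TA,CA,pctCA,Ix,Iy,Imax,Imin,J,Zx,Zy,Zp
humerus,right,20,214.8,112.9,52.6,2308,3820,3941,2187,6128,281,341,525
humerus,right,35,230.0,136.5,59.4,3648,3486,3654,3479,7134,384,394,741
humerus,right,40,221.3,134.7,60.9,3382,3292,3603,3071,6674,373,372,727
humerus,right,50,227.6,126.6,55.6,3761,2972,3927,2806,6733,389,349,695
humerus,right,65,240.9,139.8,58.0,4159,3557,4424,3291,7715,441,398,803
humerus,right,80,215.6,120.0,55.7,2993,3035,3079,2949,6028,316,332,636
humerus,left,20,213.4,117.4,55.0,2364,3753,3875,2242,6117,301,341,524
humerus,left,80,208.5,108.0,51.8,2689,2646,2745,2591,5336,274,303,542
femur,left,20,479.5,206.3,43.0,10897,13783,13895,10786,24681,919,969,1728
femur,left,35,358.1,176.0,49.1,7514,7535,7825,7224,15049,665,706,1312
femur,left,50,330.1,197.6,59.9,7221,7327,7536,7011,14548,688,691,1350
femur,left,65,329.0,200.5,60.9,6798,8015,8447,6366,14813,694,719,1246
femur,left,80,332.1,197.8,59.5,5948,9399,9864,5483,15347,616,792,1290
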