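section,method,fraction,metric,value
bbox,DCAN,50,AP@0.5,53.20
bbox,DCAN,50,AP@0.7,29.48
bbox,DCAN,75,AP@0.5,54.01
bbox,DCAN,75,AP@0.7,30.87
bbox,DCAN,100,AP@0.5,55.97
bbox,DCAN,100,AP@0.7,32.76
bbox,CosineEmbedding,50,AP@0.5,8.70
bbox,CosineEmbedding,50,AP@0.7,0.82
bbox,CosineEmbedding,75,AP@0.5,11.24
bbox,CosineEmbedding,75,AP@0.7,1.14
bbox,CosineEmbedding,100,AP@0.5,13.26
bbox,CosineEmbedding,100,AP@0.7,2.40
bbox,MaskRCNN,50,AP@0.5,70.54
bbox,MaskRCNN,50,AP@0.7,42.97
bbox,MaskRCNN,75,AP@0.5,71.03
bbox,MaskRCNN,75,AP@0.7,43.94
bbox,MaskRCNN,100,AP@0.5,72.40
bbox,MaskRCNN,100,AP@0.7,45.37
bbox,InstSeg,50,AP@0.5,74.19
bbox,InstSeg,50,AP@0.7,55.06
bbox,InstSeg,75,AP@0.5,74.22
bbox,InstSeg,75,AP@0.7,61.65
bbox,InstSeg,100,AP@0.5,74.50
bbox,InstSeg,100,AP@0.7,62.14
segmentation,DCAN,50,AP@0.5,58.1
segmentation,DCAN,50,AP@0.7,23.84
segmentation,DCAN,50,IOU@0.5,70.37
segmentation,DCAN,50,IOU@0.7,78.72
segmentation,DCAN,75,AP@0.5,64.73
segmentation,DCAN,75,AP@0.7,24.71
segmentation,DCAN,75,IOU@0.5,73.59
segmentation,DCAN,75,IOU@0.7,82.64
segmentation,DCAN,100,AP@0.5,65.50
segmentation,DCAN,100,AP@0.7,28.57
segmentation,DCAN,100,IOU@0.5,72.38
segmentation,DCAN,100,IOU@0.7,80.38
segmentation,CosineEmbedding,50,AP@0.5,21.19
segmentation,CosineEmbedding,50,AP@0.7,0.64
segmentation,CosineEmbedding,50,IOU@0.5,59.60
segmentation,CosineEmbedding,50,IOU@0.7,74.70
segmentation,CosineEmbedding,75,AP@0.5,23.08
segmentation,CosineEmbedding,75,AP@0.7,8.18
segmentation,CosineEmbedding,75,IOU@0.5,64.51
segmentation,CosineEmbedding,75,IOU@0.7,74.72
segmentation,CosineEmbedding,100,AP@0.5,23.97
segmentation,CosineEmbedding,100,AP@0.7,5.27
segmentation,CosineEmbedding,100,IOU@0.5,63.21
segmentation,CosineEmbedding,100,IOU@0.7,74.15
segmentation,MaskRCNN,50,AP@0.5,72.26
segmentation,MaskRCNN,50,AP@0.7,51.77
segmentation,MaskRCNN,50,IOU@0.5,77.95
segmentation,MaskRCNN,50,IOU@0.7,82.69
segmentation,MaskRCNN,75,AP@0.5,72.92
segmentation,MaskRCNN,75,AP@0.7,57.69
segmentation,MaskRCNN,75,IOU@0.5,78.43
segmentation,MaskRCNN,75,IOU@0.7,83.61
segmentation,MaskRCNN,100,AP@0.5,73.51
segmentation,MaskRCNN,100,AP@0.7,57.73
segmentation,MaskRCNN,100,IOU@0.5,78.07
segmentation,MaskRCNN,100,IOU@0.7,83.56
segmentation,InstSeg,50,AP@0.5,74.90
segmentation,InstSeg,50,AP@0.7,56.21
segmentation,InstSeg,50,IOU@0.5,80.37
segmentation,InstSeg,50,IOU@0.7,84.60
segmentation,InstSeg,75,AP@0.5,74.94
segmentation,InstSeg,75,AP@0.7,63.03
segmentation,InstSeg,75,IOU@0.5,81.06
segmentation,InstSeg,75,IOU@0.7,84.89
segmentation,InstSeg,100,AP@0.5,75.14
segmentation,InstSeg,100,AP@0.7,63.43
segmentation,InstSeg,100,IOU@0.5,81.09
segmentation,InstSeg,100,IOU@0.7,84.93
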