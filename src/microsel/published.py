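"""Published benchmark metric tables (prostate microarray, 59 normal / 77 tumour).

Rows are (extraction, classifier, accuracy, precision, f1, mcc, fm,
error_rate, jaccard, csi, gmean, kappa); percent-scale columns are
percentages, correlation-scale columns are on [-1, 1]. Keys name the
feature-selection stage: "none", "harmony_search", "firefly", "eho".
"""

PUBLISHED_ROWS = {
    "none": [
        ("EM", "SVM (Linear)", 55.88, 62.32, 58.90, 0.12, 0.59, 44.12, 41.75, 18.16, 55.40, 0.12),
        ("EM", "SVM (Polynomial)", 57.35, 63.77, 60.27, 0.15, 0.60, 42.65, 43.14, 20.91, 56.89, 0.15),
        ("EM", "SVM (RBF)", 69.12, 80.70, 68.66, 0.41, 0.69, 30.88, 52.27, 40.44, 70.02, 0.40),
        ("EM", "Random forest", 62.50, 68.57, 65.31, 0.25, 0.65, 37.50, 48.48, 30.91, 62.00, 0.25),
        ("EM", "Decision tree", 62.50, 67.11, 66.67, 0.24, 0.67, 37.50, 50.00, 33.34, 61.67, 0.24),
        ("EM", "QDA", 65.44, 72.06, 67.59, 0.31, 0.68, 34.56, 51.04, 35.70, 65.11, 0.31),
        ("EM", "Adaboost", 69.12, 73.97, 72.00, 0.38, 0.72, 30.88, 56.25, 44.10, 68.53, 0.38),
        ("EM", "XG boost", 72.79, 77.78, 75.17, 0.45, 0.75, 27.21, 60.22, 50.51, 72.29, 0.45),
        ("NLR", "SVM (Linear)", 58.09, 66.67, 58.39, 0.18, 0.59, 41.91, 41.24, 18.61, 58.49, 0.17),
        ("NLR", "SVM (Polynomial)", 68.38, 72.37, 71.90, 0.36, 0.72, 31.62, 56.12, 43.80, 67.70, 0.36),
        ("NLR", "SVM (RBF)", 75.74, 82.35, 77.24, 0.52, 0.77, 24.26, 62.92, 55.08, 75.45, 0.51),
        ("NLR", "Random forest", 72.06, 83.05, 72.06, 0.47, 0.73, 27.94, 56.32, 46.69, 72.70, 0.45),
        ("NLR", "Decision tree", 73.53, 83.61, 73.91, 0.49, 0.74, 26.47, 58.62, 49.84, 73.91, 0.48),
        ("NLR", "QDA", 73.53, 80.60, 75.00, 0.48, 0.75, 26.47, 60.00, 50.73, 73.30, 0.47),
        ("NLR", "Adaboost", 74.26, 76.92, 77.42, 0.48, 0.77, 25.74, 63.16, 54.85, 73.74, 0.48),
        ("NLR", "XG boost", 78.68, 82.43, 80.79, 0.57, 0.81, 21.32, 67.78, 61.65, 78.20, 0.57),
        ("KMEANS", "SVM (Linear)", 59.56, 66.67, 61.54, 0.20, 0.62, 40.44, 44.44, 23.81, 59.36, 0.19),
        ("KMEANS", "SVM (Polynomial)", 59.56, 65.71, 62.59, 0.19, 0.63, 40.44, 45.54, 25.45, 59.03, 0.19),
        ("KMEANS", "SVM (RBF)", 76.47, 84.62, 77.46, 0.54, 0.78, 23.53, 63.22, 56.04, 76.42, 0.53),
        ("KMEANS", "Random forest", 72.79, 82.26, 73.38, 0.47, 0.74, 27.21, 57.95, 48.49, 73.05, 0.46),
        ("KMEANS", "Decision tree", 57.35, 63.77, 60.27, 0.15, 0.60, 42.65, 43.14, 20.91, 56.89, 0.15),
        ("KMEANS", "QDA", 72.06, 76.71, 74.67, 0.44, 0.75, 27.94, 59.57, 49.44, 71.51, 0.44),
        ("KMEANS", "Adaboost", 72.79, 76.32, 75.82, 0.45, 0.76, 27.21, 61.05, 51.64, 72.21, 0.45),
        ("KMEANS", "XG boost", 83.82, 87.67, 85.33, 0.67, 0.85, 16.18, 74.42, 70.79, 83.41, 0.67),
        ("PCA", "SVM (Linear)", 58.82, 65.67, 61.11, 0.18, 0.61, 41.18, 44.00, 22.81, 58.54, 0.18),
        ("PCA", "SVM (Polynomial)", 57.35, 63.77, 60.27, 0.15, 0.60, 42.65, 43.14, 20.91, 56.89, 0.15),
        ("PCA", "SVM (RBF)", 72.06, 85.45, 71.21, 0.48, 0.72, 27.94, 55.29, 46.49, 73.35, 0.45),
        ("PCA", "Random forest", 66.91, 72.86, 69.39, 0.34, 0.69, 33.09, 53.13, 39.09, 66.45, 0.34),
        ("PCA", "Decision tree", 66.91, 72.22, 69.80, 0.33, 0.70, 33.09, 53.61, 39.75, 66.34, 0.33),
        ("PCA", "QDA", 72.79, 80.30, 74.13, 0.46, 0.74, 27.21, 58.89, 49.13, 72.64, 0.46),
        ("PCA", "Adaboost", 68.38, 75.00, 70.34, 0.37, 0.70, 31.62, 54.26, 41.23, 68.06, 0.37),
        ("PCA", "XG boost", 71.32, 76.39, 73.83, 0.42, 0.74, 28.68, 58.51, 47.82, 70.80, 0.42),
        ("DCT", "SVM (Linear)", 59.56, 66.18, 62.07, 0.19, 0.62, 40.44, 45.00, 24.62, 59.19, 0.19),
        ("DCT", "SVM (Polynomial)", 62.50, 68.57, 65.31, 0.25, 0.65, 37.50, 48.48, 30.91, 62.00, 0.25),
        ("DCT", "SVM (RBF)", 79.41, 86.57, 80.56, 0.60, 0.81, 20.59, 67.44, 61.89, 79.20, 0.59),
        ("DCT", "Random forest", 75.00, 75.90, 78.75, 0.49, 0.79, 25.00, 64.95, 57.72, 74.74, 0.48),
        ("DCT", "Decision tree", 83.09, 86.49, 84.77, 0.66, 0.85, 16.91, 73.56, 69.60, 82.68, 0.66),
        ("DCT", "QDA", 64.71, 70.42, 67.57, 0.29, 0.68, 35.29, 51.02, 35.36, 64.16, 0.29),
        ("DCT", "Adaboost", 72.79, 78.57, 74.83, 0.46, 0.75, 27.21, 59.78, 50.00, 72.37, 0.45),
        ("DCT", "XG boost", 86.03, 90.28, 87.25, 0.72, 0.87, 13.97, 77.38, 74.69, 85.65, 0.72),
    ],
    "harmony_search": [
        ("EM", "SVM (Linear)", 63.24, 68.00, 67.11, 0.26, 0.67, 36.77, 50.50, 34.23, 62.46, 0.26),
        ("EM", "SVM (Polynomial)", 70.59, 77.61, 72.22, 0.42, 0.72, 29.41, 56.52, 45.14, 70.35, 0.41),
        ("EM", "SVM (RBF)", 84.56, 90.00, 85.71, 0.69, 0.86, 15.44, 75.00, 71.82, 84.21, 0.69),
        ("EM", "Random forest", 82.35, 85.33, 84.21, 0.64, 0.84, 17.65, 72.73, 68.45, 81.94, 0.64),
        ("EM", "Decision tree", 72.79, 76.32, 75.82, 0.45, 0.76, 27.21, 61.05, 51.64, 72.21, 0.45),
        ("EM", "QDA", 84.56, 87.84, 86.09, 0.69, 0.86, 15.44, 75.58, 72.25, 84.17, 0.69),
        ("EM", "Adaboost", 79.41, 83.56, 81.33, 0.59, 0.81, 20.59, 68.54, 62.78, 78.96, 0.58),
        ("EM", "XG boost", 81.62, 86.11, 83.22, 0.63, 0.83, 18.38, 71.26, 66.63, 81.20, 0.63),
        ("NLR", "SVM (Linear)", 58.09, 64.71, 60.69, 0.16, 0.61, 41.91, 43.56, 21.85, 57.71, 0.16),
        ("NLR", "SVM (Polynomial)", 58.82, 64.79, 62.16, 0.17, 0.62, 41.18, 45.10, 24.53, 58.22, 0.17),
        ("NLR", "SVM (RBF)", 83.82, 85.71, 85.71, 0.67, 0.86, 16.18, 75.00, 71.43, 83.51, 0.67),
        ("NLR", "Random forest", 72.79, 83.33, 72.99, 0.48, 0.74, 27.21, 57.47, 48.27, 73.30, 0.46),
        ("NLR", "Decision tree", 73.53, 81.54, 74.65, 0.48, 0.75, 26.47, 59.55, 50.37, 73.47, 0.47),
        ("NLR", "QDA", 86.77, 89.33, 88.16, 0.73, 0.88, 13.24, 78.82, 76.35, 86.42, 0.73),
        ("NLR", "Adaboost", 80.15, 83.78, 82.12, 0.60, 0.82, 19.85, 69.66, 64.30, 79.70, 0.60),
        ("NLR", "XG boost", 83.82, 86.67, 85.53, 0.67, 0.86, 16.18, 74.71, 71.08, 83.44, 0.67),
        ("KMEANS", "SVM (Linear)", 54.41, 60.87, 57.53, 0.09, 0.58, 45.59, 40.39, 15.42, 53.92, 0.09),
        ("KMEANS", "SVM (Polynomial)", 58.82, 64.79, 62.16, 0.17, 0.62, 41.18, 45.10, 24.53, 58.22, 0.17),
        ("KMEANS", "SVM (RBF)", 72.06, 85.46, 71.21, 0.48, 0.72, 27.94, 55.29, 46.49, 73.35, 0.46),
        ("KMEANS", "Random forest", 71.32, 81.67, 71.53, 0.45, 0.72, 28.68, 55.68, 45.30, 71.82, 0.44),
        ("KMEANS", "Decision tree", 67.65, 73.24, 70.27, 0.35, 0.70, 32.35, 54.17, 40.77, 67.14, 0.35),
        ("KMEANS", "QDA", 72.06, 76.71, 74.67, 0.44, 0.75, 27.94, 59.57, 49.44, 71.51, 0.44),
        ("KMEANS", "Adaboost", 80.88, 85.92, 82.43, 0.62, 0.83, 19.12, 70.12, 65.14, 80.48, 0.62),
        ("KMEANS", "XG boost", 84.56, 87.84, 86.09, 0.69, 0.86, 15.44, 75.58, 72.25, 84.17, 0.69),
        ("PCA", "SVM (Linear)", 55.88, 62.32, 58.90, 0.12, 0.59, 44.12, 41.75, 18.16, 55.40, 0.12),
        ("PCA", "SVM (Polynomial)", 57.35, 63.77, 60.27, 0.15, 0.60, 42.65, 43.14, 20.91, 56.89, 0.15),
        ("PCA", "SVM (RBF)", 74.27, 85.00, 74.45, 0.51, 0.75, 25.74, 59.30, 51.23, 74.78, 0.49),
        ("PCA", "Random forest", 79.41, 83.56, 81.33, 0.59, 0.81, 20.59, 68.54, 62.78, 78.96, 0.58),
        ("PCA", "Decision tree", 73.53, 82.54, 74.29, 0.49, 0.75, 26.47, 59.09, 50.07, 73.67, 0.48),
        ("PCA", "QDA", 75.00, 76.54, 78.48, 0.49, 0.79, 25.00, 64.58, 57.06, 74.61, 0.49),
        ("PCA", "Adaboost", 76.47, 77.78, 79.75, 0.52, 0.80, 23.53, 66.32, 59.60, 76.14, 0.52),
        ("PCA", "XG boost", 72.79, 78.57, 74.83, 0.46, 0.75, 27.21, 59.78, 50.00, 72.38, 0.45),
        ("DCT", "SVM (Linear)", 55.88, 61.97, 59.46, 0.11, 0.60, 44.12, 42.31, 19.12, 55.24, 0.11),
        ("DCT", "SVM (Polynomial)", 58.09, 63.51, 62.25, 0.15, 0.62, 41.91, 45.19, 24.55, 57.26, 0.15),
        ("DCT", "SVM (RBF)", 80.88, 84.00, 82.90, 0.61, 0.83, 19.12, 70.79, 65.82, 80.45, 0.61),
        ("DCT", "Random forest", 73.53, 78.87, 75.68, 0.47, 0.76, 26.47, 60.87, 51.60, 73.07, 0.47),
        ("DCT", "Decision tree", 78.68, 82.43, 80.80, 0.57, 0.81, 21.32, 67.78, 61.65, 78.21, 0.57),
        ("DCT", "QDA", 84.56, 86.84, 86.28, 0.69, 0.86, 15.44, 75.86, 72.56, 84.22, 0.69),
        ("DCT", "Adaboost", 74.27, 75.00, 78.26, 0.47, 0.78, 25.74, 64.29, 56.82, 74.03, 0.47),
        ("DCT", "XG boost", 77.21, 79.49, 80.00, 0.54, 0.80, 22.79, 66.67, 60.01, 76.77, 0.54),
    ],
    "firefly": [
        ("EM", "SVM (Linear)", 60.29, 67.16, 62.50, 0.21, 0.63, 39.71, 45.46, 25.61, 60.01, 0.21),
        ("EM", "SVM (Polynomial)", 72.79, 85.71, 72.18, 0.49, 0.73, 27.21, 56.47, 48.05, 73.92, 0.47),
        ("EM", "SVM (RBF)", 72.79, 84.48, 72.59, 0.49, 0.73, 27.21, 56.98, 48.12, 73.59, 0.47),
        ("EM", "Random forest", 72.79, 83.33, 72.99, 0.48, 0.74, 27.21, 57.47, 48.27, 73.30, 0.46),
        ("EM", "Decision tree", 72.79, 78.57, 74.83, 0.46, 0.75, 27.21, 59.78, 50.00, 72.38, 0.45),
        ("EM", "QDA", 75.00, 75.90, 78.75, 0.49, 0.79, 25.00, 64.95, 57.72, 74.74, 0.49),
        ("EM", "Adaboost", 86.03, 89.19, 87.42, 0.72, 0.87, 13.97, 77.65, 74.90, 85.65, 0.72),
        ("EM", "XG boost", 86.03, 90.28, 87.25, 0.72, 0.87, 13.97, 77.38, 74.69, 85.65, 0.72),
        ("NLR", "SVM (Linear)", 66.91, 73.53, 68.97, 0.34, 0.69, 33.09, 52.63, 38.46, 66.58, 0.34),
        ("NLR", "SVM (Polynomial)", 73.53, 82.54, 74.29, 0.49, 0.75, 26.47, 59.09, 50.07, 73.67, 0.48),
        ("NLR", "SVM (RBF)", 78.68, 88.71, 79.14, 0.59, 0.80, 21.32, 65.48, 60.14, 78.95, 0.58),
        ("NLR", "Random forest", 72.79, 76.32, 75.82, 0.45, 0.76, 27.21, 61.05, 51.64, 72.21, 0.45),
        ("NLR", "Decision tree", 78.68, 83.33, 80.54, 0.57, 0.81, 21.32, 67.42, 61.26, 78.23, 0.57),
        ("NLR", "QDA", 82.35, 86.30, 84.00, 0.65, 0.84, 17.65, 72.41, 68.12, 81.93, 0.64),
        ("NLR", "Adaboost", 85.29, 89.04, 86.67, 0.70, 0.87, 14.71, 76.47, 73.46, 84.90, 0.70),
        ("NLR", "XG boost", 88.97, 89.74, 90.32, 0.78, 0.90, 11.03, 82.35, 80.65, 88.83, 0.78),
        ("KMEANS", "SVM (Linear)", 56.62, 62.86, 59.86, 0.13, 0.60, 43.38, 42.72, 20.00, 56.06, 0.13),
        ("KMEANS", "SVM (Polynomial)", 57.35, 63.77, 60.27, 0.15, 0.60, 42.65, 43.14, 20.91, 56.89, 0.15),
        ("KMEANS", "SVM (RBF)", 73.53, 88.68, 72.31, 0.52, 0.74, 26.47, 56.63, 49.72, 75.25, 0.49),
        ("KMEANS", "Random forest", 83.82, 85.71, 85.71, 0.67, 0.86, 16.18, 75.00, 71.43, 83.51, 0.67),
        ("KMEANS", "Decision tree", 73.53, 76.62, 76.62, 0.46, 0.77, 26.47, 62.11, 53.25, 72.97, 0.46),
        ("KMEANS", "QDA", 75.74, 76.83, 79.25, 0.50, 0.79, 24.27, 65.63, 58.65, 75.44, 0.50),
        ("KMEANS", "Adaboost", 83.82, 87.67, 85.33, 0.67, 0.85, 16.18, 74.42, 70.79, 83.42, 0.67),
        ("KMEANS", "XG boost", 86.03, 88.16, 87.58, 0.72, 0.88, 13.97, 77.91, 75.17, 85.71, 0.72),
        ("PCA", "SVM (Linear)", 57.35, 64.62, 59.16, 0.15, 0.59, 42.65, 42.00, 19.16, 57.24, 0.15),
        ("PCA", "SVM (Polynomial)", 58.82, 66.67, 60.00, 0.19, 0.60, 41.18, 42.86, 21.21, 58.91, 0.18),
        ("PCA", "SVM (RBF)", 85.29, 92.54, 86.11, 0.71, 0.86, 14.71, 75.61, 73.06, 85.10, 0.71),
        ("PCA", "Random forest", 60.29, 67.69, 61.97, 0.21, 0.62, 39.71, 44.90, 24.84, 60.19, 0.21),
        ("PCA", "Decision tree", 72.06, 85.46, 71.21, 0.48, 0.72, 27.94, 55.29, 46.49, 73.35, 0.46),
        ("PCA", "QDA", 73.53, 82.54, 74.29, 0.49, 0.75, 26.47, 59.09, 50.07, 73.67, 0.48),
        ("PCA", "Adaboost", 73.53, 83.61, 73.91, 0.49, 0.74, 26.47, 58.62, 49.84, 73.91, 0.48),
        ("PCA", "XG boost", 81.62, 80.95, 84.47, 0.62, 0.85, 18.38, 73.12, 69.26, 81.82, 0.62),
        ("DCT", "SVM (Linear)", 72.79, 80.30, 74.13, 0.46, 0.74, 27.21, 58.89, 49.13, 72.64, 0.46),
        ("DCT", "SVM (Polynomial)", 72.06, 77.47, 74.32, 0.44, 0.74, 27.94, 59.14, 48.89, 71.59, 0.44),
        ("DCT", "SVM (RBF)", 74.27, 78.38, 76.82, 0.48, 0.77, 25.74, 62.37, 53.70, 73.73, 0.48),
        ("DCT", "Random forest", 75.00, 76.54, 78.48, 0.49, 0.79, 25.00, 64.58, 57.06, 74.61, 0.49),
        ("DCT", "Decision tree", 75.00, 75.90, 78.75, 0.49, 0.79, 25.00, 64.95, 57.72, 74.74, 0.49),
        ("DCT", "QDA", 83.82, 86.67, 85.53, 0.67, 0.86, 16.18, 74.71, 71.08, 83.44, 0.67),
        ("DCT", "Adaboost", 85.29, 88.00, 86.84, 0.70, 0.87, 14.71, 76.74, 73.71, 84.93, 0.70),
        ("DCT", "XG boost", 86.03, 89.19, 87.42, 0.72, 0.87, 13.97, 77.65, 74.90, 85.65, 0.72),
    ],
    "eho": [
        ("EM", "SVM (Linear)", 56.62, 62.86, 59.86, 0.13, 0.60, 43.38, 42.72, 20.00, 56.06, 0.13),
        ("EM", "SVM (Polynomial)", 61.77, 67.61, 64.87, 0.23, 0.65, 38.24, 48.00, 29.94, 61.19, 0.23),
        ("EM", "SVM (RBF)", 86.03, 88.16, 87.58, 0.72, 0.88, 13.97, 77.91, 75.17, 85.71, 0.72),
        ("EM", "Random forest", 73.53, 76.62, 76.62, 0.46, 0.77, 26.47, 62.11, 53.25, 72.97, 0.46),
        ("EM", "Decision tree", 74.27, 76.25, 77.71, 0.47, 0.78, 25.74, 63.54, 55.47, 73.80, 0.47),
        ("EM", "QDA", 83.82, 87.67, 85.33, 0.67, 0.85, 16.18, 74.42, 70.79, 83.42, 0.67),
        ("EM", "Adaboost", 85.29, 89.04, 86.67, 0.70, 0.87, 14.71, 76.47, 73.46, 84.90, 0.70),
        ("EM", "XG boost", 88.24, 90.67, 89.47, 0.76, 0.90, 11.77, 80.95, 78.98, 87.92, 0.76),
        ("NLR", "SVM (Linear)", 57.35, 63.77, 60.27, 0.15, 0.60, 42.65, 43.14, 20.91, 56.89, 0.15),
        ("NLR", "SVM (Polynomial)", 72.79, 79.41, 74.48, 0.46, 0.75, 27.21, 59.34, 49.54, 72.49, 0.46),
        ("NLR", "SVM (RBF)", 86.77, 87.34, 88.46, 0.73, 0.89, 13.24, 79.31, 76.95, 86.65, 0.73),
        ("NLR", "Random forest", 83.09, 86.49, 84.77, 0.66, 0.85, 16.91, 73.56, 69.60, 82.68, 0.66),
        ("NLR", "Decision tree", 84.56, 86.84, 86.28, 0.69, 0.86, 15.44, 75.86, 72.56, 84.22, 0.69),
        ("NLR", "QDA", 77.21, 77.38, 80.75, 0.53, 0.81, 22.79, 67.71, 61.80, 77.15, 0.53),
        ("NLR", "Adaboost", 75.00, 76.54, 78.48, 0.49, 0.79, 25.00, 64.58, 57.06, 74.61, 0.49),
        ("NLR", "XG boost", 88.24, 90.67, 89.47, 0.76, 0.90, 11.77, 80.95, 78.98, 87.92, 0.76),
        ("KMEANS", "SVM (Linear)", 63.97, 70.59, 66.21, 0.28, 0.66, 36.03, 49.49, 32.93, 63.63, 0.28),
        ("KMEANS", "SVM (Polynomial)", 58.09, 64.29, 61.22, 0.16, 0.61, 41.91, 44.12, 22.73, 57.55, 0.16),
        ("KMEANS", "SVM (RBF)", 90.44, 93.24, 91.39, 0.81, 0.91, 9.56, 84.15, 82.85, 90.12, 0.81),
        ("KMEANS", "Random forest", 75.00, 81.16, 76.71, 0.50, 0.77, 25.00, 62.22, 53.89, 74.65, 0.50),
        ("KMEANS", "Decision tree", 75.00, 76.54, 78.48, 0.49, 0.79, 25.00, 64.58, 57.06, 74.61, 0.49),
        ("KMEANS", "QDA", 75.00, 75.29, 79.01, 0.49, 0.79, 25.00, 65.31, 58.41, 74.90, 0.48),
        ("KMEANS", "Adaboost", 72.79, 76.32, 75.82, 0.45, 0.76, 27.21, 61.05, 51.64, 72.21, 0.45),
        ("KMEANS", "XG boost", 81.62, 83.33, 83.87, 0.63, 0.84, 18.38, 72.22, 67.75, 81.30, 0.63),
        ("PCA", "SVM (Linear)", 72.06, 78.26, 73.97, 0.44, 0.74, 27.94, 58.70, 48.39, 71.69, 0.44),
        ("PCA", "SVM (Polynomial)", 63.97, 68.92, 67.55, 0.27, 0.68, 36.03, 51.00, 35.15, 63.26, 0.27),
        ("PCA", "SVM (RBF)", 91.18, 93.33, 92.11, 0.82, 0.92, 8.82, 85.37, 84.24, 90.90, 0.82),
        ("PCA", "Random forest", 84.56, 87.84, 86.09, 0.69, 0.86, 15.44, 75.58, 72.25, 84.17, 0.69),
        ("PCA", "Decision tree", 84.56, 87.84, 86.09, 0.69, 0.86, 15.44, 75.58, 72.25, 84.17, 0.69),
        ("PCA", "QDA", 88.24, 90.67, 89.47, 0.76, 0.90, 11.77, 80.95, 78.98, 87.92, 0.76),
        ("PCA", "Adaboost", 89.71, 92.00, 90.79, 0.79, 0.91, 10.29, 83.13, 81.61, 89.41, 0.79),
        ("PCA", "XG boost", 91.18, 93.33, 92.11, 0.82, 0.92, 8.82, 85.37, 84.24, 90.90, 0.82),
        ("DCT", "SVM (Linear)", 63.24, 68.49, 66.67, 0.26, 0.67, 36.77, 50.00, 33.43, 62.56, 0.26),
        ("DCT", "SVM (Polynomial)", 72.06, 80.00, 73.24, 0.45, 0.74, 27.94, 57.78, 47.53, 71.99, 0.44),
        ("DCT", "SVM (RBF)", 94.85, 97.30, 95.36, 0.90, 0.95, 5.15, 91.14, 90.80, 94.58, 0.90),
        ("DCT", "Random forest", 80.88, 84.00, 82.90, 0.61, 0.83, 19.12, 70.79, 65.82, 80.45, 0.61),
        ("DCT", "Decision tree", 88.24, 91.78, 89.33, 0.76, 0.89, 11.77, 80.72, 78.79, 87.87, 0.76),
        ("DCT", "QDA", 90.44, 93.24, 91.39, 0.81, 0.91, 9.56, 84.15, 82.85, 90.12, 0.81),
        ("DCT", "Adaboost", 91.91, 94.60, 92.72, 0.84, 0.93, 8.09, 86.42, 85.50, 91.61, 0.84),
        ("DCT", "XG boost", 94.12, 98.59, 94.60, 0.89, 0.95, 5.88, 89.74, 89.50, 93.79, 0.88),
    ],
}

PUBLISHED_COLUMNS = (
    "extraction", "classifier", "accuracy", "precision", "f1", "mcc", "fm",
    "error_rate", "jaccard", "csi", "gmean", "kappa",
)

#: class totals of the benchmark (positive = tumour)
N_POSITIVE = 77
N_NEGATIVE = 59


def accuracies(selection: str) -> list[float]:
    """The 40 printed accuracy values of one selection table."""
    return [row[2] for row in PUBLISHED_ROWS[selection]]


def mcc_kappa_pairs() -> list[tuple[float, float]]:
    """(MCC, Kappa) pairs pooled over all four published tables."""
    return [(row[5], row[11]) for rows in PUBLISHED_ROWS.values() for row in rows]


def published_row(selection: str, extraction: str, classifier: str) -> dict:
    """One published row as a column-name → value mapping."""
    for row in PUBLISHED_ROWS[selection]:
        if row[0] == extraction and row[1] == classifier:
            return dict(zip(PUBLISHED_COLUMNS, row))
    raise KeyError(f"no published row {selection}/{extraction}/{classifier}")
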